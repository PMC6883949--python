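"""Transcript models, lncRNA candidate filtering and positional classification.

Internally every coordinate is 1-based inclusive (GTF convention). BED input
is converted on read (start + 1). The candidate filter and the positional
classifier mirror the first annotation step of lncRNA prediction tools:
novel transcripts are kept when they are at least 200 nt of exonic sequence
and either multi-exonic, or mono-exonic but antisense to an annotated gene;
each surviving lncRNA is then assigned its best positional partner gene
(genic: overlapping, preferably at an exon; intergenic: closest gene within
a 100 kb window).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import pandas as pd
from intervaltree import IntervalTree

GENIC_WINDOW = (10_000, 100_000)


@dataclass
class TranscriptModel:
    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]  # 1-based inclusive, sorted, non-overlapping
    biotype: str

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript without exons")
        self.exons = sorted((int(s), int(e)) for s, e in self.exons)
        prev_end = 0
        for s, e in self.exons:
            if s > e:
                raise ValueError(f"{self.transcript_id}: exon start > end")
            if s <= prev_end:
                raise ValueError(f"{self.transcript_id}: overlapping/unsorted exons")
            prev_end = e

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def exonic_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)


@dataclass
class LncRNAClassification:
    lncrna_id: str
    partner_gene_id: str | None
    direction: str | None  # sense / antisense
    type: str | None  # genic / intergenic
    subtype: str | None  # exonic / intronic / containing / upstream / downstream
    distance_bp: int | None  # 0 for genic, gap in bp for intergenic


@dataclass
class QTLInterval:
    chrom: str
    start: int  # 1-based inclusive
    end: int
    trait: str  # RFI or MY

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("QTL interval start > end")


# ---------------------------------------------------------------------------
# GTF / BED I/O
# ---------------------------------------------------------------------------

def write_gtf(transcripts: Iterable[TranscriptModel], path: str | Path) -> None:
    """Write transcript and exon records as 9-column GTF."""
    with open(path, "w") as fh:
        for tx in transcripts:
            attrs = (
                f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}"; '
                f'biotype "{tx.biotype}";'
            )
            fh.write(
                "\t".join(
                    [tx.chrom, "lncnet", "transcript", str(tx.start), str(tx.end),
                     ".", tx.strand, ".", attrs]
                )
                + "\n"
            )
            for s, e in tx.exons:
                fh.write(
                    "\t".join(
                        [tx.chrom, "lncnet", "exon", str(s), str(e), ".", tx.strand,
                         ".", attrs]
                    )
                    + "\n"
                )


def read_gtf(path: str | Path) -> list[TranscriptModel]:
    """Read transcript models (grouped exons) from a GTF file."""
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        merge_strategy="create_unique",
    )
    grouped: dict[str, dict] = {}
    for exon in db.features_of_type("exon", order_by=("seqid", "start")):
        tid = exon.attributes["transcript_id"][0]
        rec = grouped.setdefault(
            tid,
            {
                "gene_id": exon.attributes["gene_id"][0],
                "chrom": exon.seqid,
                "strand": exon.strand,
                "biotype": exon.attributes.get("biotype", ["."])[0],
                "exons": [],
            },
        )
        rec["exons"].append((exon.start, exon.end))
    return [
        TranscriptModel(transcript_id=tid, exons=rec["exons"], gene_id=rec["gene_id"],
                        chrom=rec["chrom"], strand=rec["strand"], biotype=rec["biotype"])
        for tid, rec in grouped.items()
    ]


def read_bed(path: str | Path, trait_column: int | None = 3) -> list[QTLInterval]:
    """Read BED (0-based half-open) intervals, converting to 1-based inclusive."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            trait = parts[trait_column] if trait_column is not None and len(parts) > trait_column else "."
            out.append(QTLInterval(chrom=chrom, start=start + 1, end=end, trait=trait))
    return out


def write_bed(intervals: Iterable[QTLInterval], path: str | Path) -> None:
    """Write intervals as BED (converting 1-based inclusive back to 0-based half-open)."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t{iv.trait}\n")


# ---------------------------------------------------------------------------
# Candidate filtering
# ---------------------------------------------------------------------------

def _overlaps(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    return a_start <= b_end and b_start <= a_end


def filter_lncrna_candidates(
    transcripts: Sequence[TranscriptModel],
    reference: Sequence[TranscriptModel],
) -> list[TranscriptModel]:
    """Keep novel transcripts that qualify as lncRNA candidates.

    Rules: drop anything annotated protein-coding; keep transcripts with
    exonic length >= 200 nt that are multi-exonic, or mono-exonic but
    overlapping an annotated gene on the opposite strand. All other
    mono-exonic transcripts are dropped (likely mapping artefacts).
    """
    ref_by_chrom: dict[str, list[TranscriptModel]] = {}
    for ref in reference:
        ref_by_chrom.setdefault(ref.chrom, []).append(ref)

    kept = []
    for tx in transcripts:
        if tx.biotype == "protein_coding":
            continue
        if tx.exonic_length < 200:
            continue
        if tx.n_exons >= 2:
            kept.append(tx)
            continue
        # mono-exonic: antisense overlap with an annotated gene required
        antisense = any(
            ref.strand != tx.strand and _overlaps(tx.start, tx.end, ref.start, ref.end)
            for ref in ref_by_chrom.get(tx.chrom, [])
        )
        if antisense:
            kept.append(tx)
    return kept


# ---------------------------------------------------------------------------
# Positional classification
# ---------------------------------------------------------------------------

def _gap(a: TranscriptModel, b: TranscriptModel) -> int:
    """Intervening bases between two non-overlapping features."""
    if a.start > b.end:
        a, b = b, a
    return b.start - a.end - 1


def _genic_subtype(lnc: TranscriptModel, gene: TranscriptModel) -> tuple[str, int]:
    """Return (subtype, exon-overlap bp) for an overlapping lnc/gene pair."""
    overlap_bp = 0
    for ls, le in lnc.exons:
        for gs, ge in gene.exons:
            if _overlaps(ls, le, gs, ge):
                overlap_bp += min(le, ge) - max(ls, gs) + 1
    if overlap_bp > 0:
        return "exonic", overlap_bp
    if lnc.start <= gene.start and gene.end <= lnc.end:
        return "containing", 0
    return "intronic", 0


_SUBTYPE_RANK = {"exonic": 0, "intronic": 1, "containing": 2}


def classify_lncrna(
    lnc: TranscriptModel,
    genes: Sequence[TranscriptModel],
    window: tuple[int, int] = GENIC_WINDOW,
) -> LncRNAClassification:
    """Assign the best positional partner gene of a lncRNA.

    Overlapping genes win (genic; exonic preferred over intronic over
    containing, ties by larger exon overlap then gene id). Otherwise the
    closest gene whose gap is within the outer window bound (default
    100 kb) is the partner; lncRNAs without any gene inside the window have
    no partner.
    """
    same_chrom = [g for g in genes if g.chrom == lnc.chrom and g.gene_id != lnc.gene_id]

    overlapping = [g for g in same_chrom if _overlaps(lnc.start, lnc.end, g.start, g.end)]
    if overlapping:
        ranked = []
        for g in overlapping:
            subtype, exon_bp = _genic_subtype(lnc, g)
            span_overlap = min(lnc.end, g.end) - max(lnc.start, g.start) + 1
            ranked.append((_SUBTYPE_RANK[subtype], -exon_bp, -span_overlap, g.gene_id, subtype, g))
        ranked.sort(key=lambda t: t[:4])
        _, _, _, _, subtype, best = ranked[0]
        direction = "sense" if best.strand == lnc.strand else "antisense"
        return LncRNAClassification(lnc.transcript_id, best.gene_id, direction,
                                    "genic", subtype, 0)

    candidates = [(g, _gap(lnc, g)) for g in same_chrom]
    candidates = [(g, d) for g, d in candidates if d <= window[1]]
    if not candidates:
        return LncRNAClassification(lnc.transcript_id, None, None, None, None, None)
    candidates.sort(key=lambda t: (t[1], t[0].gene_id))
    best, dist = candidates[0]
    direction = "sense" if best.strand == lnc.strand else "antisense"
    # upstream/downstream relative to the partner gene's orientation
    lnc_before = lnc.end < best.start
    if best.strand == "+":
        subtype = "upstream" if lnc_before else "downstream"
    else:
        subtype = "downstream" if lnc_before else "upstream"
    return LncRNAClassification(lnc.transcript_id, best.gene_id, direction,
                                "intergenic", subtype, dist)


def classification_report(records: Iterable[LncRNAClassification]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "lncrna_id": r.lncrna_id,
                "partner_gene_id": r.partner_gene_id or "",
                "direction": r.direction or "",
                "type": r.type or "",
                "subtype": r.subtype or "",
                "distance_bp": "" if r.distance_bp is None else r.distance_bp,
            }
            for r in records
        ]
    )


# ---------------------------------------------------------------------------
# QTL overlap
# ---------------------------------------------------------------------------

def flag_qtl_overlap(
    genes: Sequence[TranscriptModel] | pd.DataFrame,
    qtls: Sequence[QTLInterval],
) -> pd.DataFrame:
    """Flag genes physically overlapping (>= 1 bp) a QTL interval, per trait.

    ``genes`` is either a list of transcript models or a frame with columns
    gene_id/chrom/start/end. Adjacency is not overlap.
    """
    if isinstance(genes, pd.DataFrame):
        gene_rows = genes[["gene_id", "chrom", "start", "end"]].itertuples(index=False)
        gene_rows = [(g.gene_id, g.chrom, int(g.start), int(g.end)) for g in gene_rows]
    else:
        gene_rows = [(g.gene_id, g.chrom, g.start, g.end) for g in genes]

    traits = sorted({q.trait for q in qtls})
    trees: dict[tuple[str, str], IntervalTree] = {}
    for q in qtls:
        # half-open tree coordinates: [start, end + 1)
        trees.setdefault((q.trait, q.chrom), IntervalTree()).addi(q.start, q.end + 1)

    records = []
    for gene_id, chrom, start, end in gene_rows:
        flags = {
            trait: bool(trees.get((trait, chrom), IntervalTree()).overlap(start, end + 1))
            for trait in traits
        }
        records.append({"gene_id": gene_id, **flags})
    out = pd.DataFrame(records)
    if out.empty:
        out = pd.DataFrame(columns=["gene_id", *traits])
    return out.set_index("gene_id")
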