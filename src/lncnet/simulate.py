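"""Synthetic multi-tissue cohort generator with planted ground truth.

The generator emulates the structure of the emulated study: 48 animals
(24 per sex) in high/low metabolic-efficiency groups of 25/23, four tissues,
FPKM-scale abundances with lncRNAs drawn systematically lower than mRNAs,
differential expression planted in three of the four tissues (none in
rumen), tissue-enriched genes, QTL intervals overlapping a subset of genes,
planted regulator lncRNAs whose correlation to a target module differs
between the groups (differential wiring), and plasma metabolites linearly
linked to planted regulators with below-detection missingness.

Expression is generated on the log2-FPKM scale as

    baseline + tissue offset + sex/year covariate effects
    + group effect (DE genes) + wiring term (planted modules) + noise

then back-transformed and Poisson-sampled into fragment counts with
mean = FPKM x length_kb x library_size / 1e6. All randomness flows from a
single root seed through named substreams so components can be regenerated
independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import QTLInterval, TranscriptModel, flag_qtl_overlap, write_bed, write_gtf
from .config import SimulationConfig
from .expression import CountMatrix
from .phenotypes import PopulationStats, compute_ecm, compute_rfi, metabolic_midweight

# named substreams of the root seed
_STREAMS = {"layout": 0, "expression": 1, "counts": 2, "metabolites": 3,
            "missing": 4, "phenotypes": 5, "qtl": 6}

_N_STRUCTURAL = 8  # rRNA/snoRNA/snRNA/Y-RNA loci planted to exercise biotype exclusion
_N_DECOYS = 12  # novel transcripts that must fail the lncRNA candidate filter


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAMS[stream]]))


@dataclass
class GroundTruth:
    planted_regulator_ids: list[str]
    target_map: dict[str, list[str]]
    de_gene_ids: dict[str, list[str]]  # tissue -> genes (includes planted targets)
    ts_gene_ids: dict[str, list[str]]
    qtl_gene_ids: dict[str, list[str]]  # trait -> genes
    lncrna_ids: list[str]  # all true lncRNA loci (candidate-filter survivors)
    decoy_ids: list[str]
    isolated_lnc_ids: list[str]
    genic_lnc_ids: list[str]
    metabolite_links: dict[str, list[tuple[str, int]]]  # regulator -> [(metabolite, sign)]
    regulator_best_tissue: dict[str, str]


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    counts: dict[str, pd.DataFrame]  # tissue -> genes x animals integer counts
    annotation: list[TranscriptModel]
    gene_table: pd.DataFrame  # gene_id, chrom, start, end, strand, biotype, length
    phenotypes: pd.DataFrame
    population: PopulationStats
    metabolites: pd.DataFrame  # metabolite x animal, NaN = missing
    qtl: list[QTLInterval]
    ground_truth: GroundTruth

    def animals(self) -> list[str]:
        return list(self.phenotypes["animal_id"])

    def to_count_matrix(self) -> CountMatrix:
        """Concatenate tissues into one genes x (animal, tissue) count matrix."""
        pheno = self.phenotypes.set_index("animal_id")
        blocks, meta = [], []
        for tissue in self.config.tissues:
            block = self.counts[tissue].copy()
            block.columns = [f"{a}.{tissue}" for a in block.columns]
            blocks.append(block)
            for animal in self.counts[tissue].columns:
                meta.append(
                    {
                        "sample_id": f"{animal}.{tissue}",
                        "animal": animal,
                        "tissue": tissue,
                        "sex": pheno.loc[animal, "sex"],
                        "group": pheno.loc[animal, "group_true"],
                        "year": int(pheno.loc[animal, "year"]),
                    }
                )
        fragments = pd.concat(blocks, axis=1)
        sample_meta = pd.DataFrame(meta).set_index("sample_id")
        lengths = self.gene_table.set_index("gene_id")["length"]
        return CountMatrix(fragments=fragments, sample_meta=sample_meta, gene_lengths=lengths)


# ---------------------------------------------------------------------------
# genome layout
# ---------------------------------------------------------------------------

def _make_exons(rng: np.random.Generator, start: int, exonic_len: int, n_exons: int,
                max_span: int | None = None) -> list[tuple[int, int]]:
    """Split ``exonic_len`` into ``n_exons`` exons with random introns."""
    n_exons = max(1, min(n_exons, exonic_len // 50))
    cuts = np.sort(rng.choice(np.arange(1, exonic_len), size=n_exons - 1, replace=False)) \
        if n_exons > 1 else np.array([], dtype=int)
    pieces = np.diff(np.concatenate([[0], cuts, [exonic_len]]))
    introns = rng.integers(200, 2000, size=n_exons - 1) if n_exons > 1 else []
    if max_span is not None and n_exons > 1:
        budget = max_span - exonic_len
        if budget <= (n_exons - 1) * 50:
            introns = np.full(n_exons - 1, max(1, budget // max(1, n_exons - 1)))
        else:
            introns = np.minimum(introns, budget // (n_exons - 1))
    exons, pos = [], start
    for i, piece in enumerate(pieces):
        exons.append((pos, pos + int(piece) - 1))
        pos += int(piece)
        if i < n_exons - 1:
            pos += int(introns[i])
    return exons


def _build_layout(cfg: SimulationConfig, rng: np.random.Generator):
    """Place genes, lncRNAs and decoys on 5 chromosomes; return transcript models."""
    n_mrna = cfg.n_genes - cfg.n_lncrna
    n_coding = n_mrna - _N_STRUCTURAL
    coding_ids = [f"GENE{i + 1:04d}" for i in range(n_coding)]
    structural = [(f"STRUCT{i + 1:02d}", ("rRNA", "snoRNA", "snRNA", "Y_RNA")[i % 4])
                  for i in range(_N_STRUCTURAL)]
    lnc_ids = [f"LNC{i + 1:04d}" for i in range(cfg.n_lncrna)]

    n_iso = max(2, int(0.1 * cfg.n_lncrna))
    lnc_classes = {}
    for i, lid in enumerate(lnc_ids):
        if i < cfg.n_planted_regulators:
            lnc_classes[lid] = "intergenic"
        elif i >= cfg.n_lncrna - n_iso:
            lnc_classes[lid] = "isolated"
        else:
            lnc_classes[lid] = "genic" if rng.random() < 0.35 else "intergenic"

    decoys = [(f"NOV{i + 1:02d}", "mono_sense" if i < _N_DECOYS // 2 else "short")
              for i in range(_N_DECOYS)]

    main_queue = [(lid, lnc_classes[lid]) for lid in lnc_ids if lnc_classes[lid] != "isolated"]
    main_queue += [(did, kind) for did, kind in decoys]
    host_genes = [(gid, "protein_coding") for gid in coding_ids] + structural
    interval = max(1, len(host_genes) // (len(main_queue) + 1))

    models: list[TranscriptModel] = []
    chroms = ["1", "2", "3", "4"]
    per_chrom = int(np.ceil(len(host_genes) / len(chroms)))
    qi = 0  # queue index
    for ci, chrom in enumerate(chroms):
        cursor = 10_000
        for gid, biotype in host_genes[ci * per_chrom:(ci + 1) * per_chrom]:
            exonic_len = int(rng.integers(500, 10_001))
            n_exons = 1 if biotype != "protein_coding" else int(rng.integers(2, 13))
            strand = "+" if rng.random() < 0.5 else "-"
            exons = _make_exons(rng, cursor, exonic_len, n_exons)
            host = TranscriptModel(f"{gid}.1", gid, chrom, strand, exons, biotype)
            models.append(host)
            cursor = host.end + 1
            placed_index = len([m for m in models if m.biotype != "novel"])
            if qi < len(main_queue) and placed_index % interval == 0:
                lid, kind = main_queue[qi]
                qi += 1
                models.append(_place_novel(rng, lid, kind, host))
                cursor = max(cursor, models[-1].end + 1)
            cursor += int(rng.integers(5_000, 40_000))
    # anything left in the queue: append as intergenic after the last gene
    while qi < len(main_queue):
        lid, kind = main_queue[qi]
        qi += 1
        last = models[-1]
        models.append(_place_novel(rng, lid, kind, last, force_intergenic=True))

    # isolated lncRNAs on a gene-poor chromosome, > 100 kb from anything
    cursor = 200_000
    for lid in lnc_ids:
        if lnc_classes[lid] != "isolated":
            continue
        exonic_len = int(rng.integers(300, 2_000))
        strand = "+" if rng.random() < 0.5 else "-"
        exons = _make_exons(rng, cursor, exonic_len, int(rng.integers(2, 5)))
        models.append(TranscriptModel(f"{lid}.1", lid, "5", strand, exons, "novel"))
        cursor = models[-1].end + 300_000

    gt_classes = {
        "genic": [l for l, c in lnc_classes.items() if c == "genic"],
        "isolated": [l for l, c in lnc_classes.items() if c == "isolated"],
    }
    return models, coding_ids, [s for s, _ in structural], lnc_ids, \
        [d for d, _ in decoys], gt_classes


def _place_novel(rng, lid, kind, host, force_intergenic=False) -> TranscriptModel:
    chrom = host.chrom
    if kind == "genic" and not force_intergenic:
        span = host.end - host.start + 1
        lnc_len = int(min(rng.integers(250, 1500), max(210, span - 10)))
        start = int(host.start + rng.integers(0, max(1, span - lnc_len)))
        strand = "-" if host.strand == "+" else "+"
        n_exons = 1 if rng.random() < 0.5 else 2
        exons = _make_exons(rng, start, lnc_len, n_exons, max_span=host.end - start + 1)
        return TranscriptModel(f"{lid}.1", lid, chrom, strand, exons, "novel")
    gap = int(rng.integers(200, 60_000))
    start = host.end + 1 + gap
    strand = "+" if rng.random() < 0.5 else "-"
    if kind == "mono_sense":  # decoy: mono-exonic, no antisense overlap -> filtered out
        exons = [(start, start + 399)]
    elif kind == "short":  # decoy: multi-exonic but < 200 nt exonic
        exons = _make_exons(rng, start, 150, 2)
    else:
        exons = _make_exons(rng, start, int(rng.integers(300, 3_000)), int(rng.integers(2, 6)))
    return TranscriptModel(f"{lid}.1", lid, chrom, strand, exons, "novel")


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

def _wiring_loading(r: float, noise_sd: float) -> float:
    """Target loading beta on a unit-variance factor giving corr ~ r at noise_sd."""
    r = float(np.clip(r, -0.999, 0.999))
    return r * noise_sd / np.sqrt(1.0 - r * r)


def _trunc_normal(rng, mean, sd, lo=-np.inf, hi=np.inf) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(mean, lo, hi))


def simulate_cohort(config: SimulationConfig) -> SyntheticDataset:
    """Generate the full synthetic dataset; fully determined by config.seed."""
    config.validate()
    seed = config.seed

    models, coding_ids, structural_ids, lnc_ids, decoy_ids, gt_classes = \
        _build_layout(config, _rng(seed, "layout"))
    gene_table = pd.DataFrame(
        [
            {
                "gene_id": m.gene_id, "chrom": m.chrom, "start": m.start, "end": m.end,
                "strand": m.strand, "biotype": m.biotype, "length": m.exonic_length,
            }
            for m in models
        ]
    )

    # ---- animals -------------------------------------------------------
    n_high, n_low = config.group_sizes
    males = [f"A{i + 1:03d}" for i in range(config.n_per_sex)]
    females = [f"A{i + 1 + config.n_per_sex:03d}" for i in range(config.n_per_sex)]
    m_high = n_high // 2
    f_high = n_high - m_high
    groups = {}
    for i, a in enumerate(males):
        groups[a] = "high" if i < m_high else "low"
    for i, a in enumerate(females):
        groups[a] = "high" if i < f_high else "low"
    animals = males + females
    years = {a: 1 + (i % 2) for i, a in enumerate(animals)}

    # ---- role assignment ----------------------------------------------
    rng_e = _rng(seed, "expression")
    pool = list(coding_ids)
    rng_e.shuffle(pool)
    regulators = lnc_ids[: config.n_planted_regulators]
    target_map = {}
    for reg in regulators:
        target_map[reg] = [pool.pop() for _ in range(config.targets_per_regulator)]
    de_tissues = list(config.tissues[:3])  # no DE planted in the last tissue
    de_gene_ids = {t: [] for t in config.tissues}
    for t in de_tissues:
        de_gene_ids[t].extend(pool.pop() for _ in range(config.n_de_per_tissue))
    ts_gene_ids = {t: [pool.pop() for _ in range(config.n_ts_per_tissue)]
                   for t in config.tissues}

    all_genes = list(gene_table["gene_id"])
    idx = {g: i for i, g in enumerate(all_genes)}
    n_rows = len(all_genes)
    n_anim = config.n_animals

    # ---- baselines -----------------------------------------------------
    baseline = np.empty(n_rows)
    coding_set = set(coding_ids)
    lnc_set = set(lnc_ids)
    target_all = {g for ts in target_map.values() for g in ts}
    ts_all = {g for ts in ts_gene_ids.values() for g in ts}
    reg_set = set(regulators)
    structural_set = set(structural_ids)
    for g, i in idx.items():
        if g in reg_set:
            baseline[i] = rng_e.normal(4.5, 0.3)
        elif g in target_all:
            # planted targets sit comfortably above the above-average
            # abundance filters so the module survives to the network stage
            baseline[i] = rng_e.normal(4.5, 0.5)
        elif g in ts_all:
            baseline[i] = _trunc_normal(rng_e, 2.5, 0.5, hi=3.8)
        elif g in lnc_set:
            baseline[i] = rng_e.normal(1.0, 1.2)
        elif g in coding_set:
            baseline[i] = rng_e.normal(3.5, 1.5)
        elif g in structural_set:
            baseline[i] = rng_e.normal(2.0, 1.0)
        else:  # decoys
            baseline[i] = rng_e.normal(0.0, 0.5)

    # tissue offsets: flat for planted modules; enrichment pattern for TS genes
    tissue_off = rng_e.normal(0.0, 1.0, size=(n_rows, len(config.tissues)))
    flat = [idx[g] for g in (*regulators, *sorted(target_all))]
    tissue_off[flat, :] = 0.0
    for tcol, t in enumerate(config.tissues):
        for g in ts_gene_ids[t]:
            # enriched tissue well above, all others pinned near-silent on an
            # absolute scale (the "below half the average" rule is not
            # shift-invariant, so relative offsets would not survive the
            # FPKM back-transform)
            tissue_off[idx[g], :] = -2.0 - baseline[idx[g]]
            tissue_off[idx[g], tcol] = 4.0

    # sex / year covariate effects on a random 10% of genes; planted module
    # genes stay clean so the wiring parameter keeps its stated meaning
    sex_genes = rng_e.random(n_rows) < 0.1
    sex_eff = np.where(sex_genes, rng_e.normal(0.0, 0.5, n_rows), 0.0)
    year_genes = rng_e.random(n_rows) < 0.1
    year_eff = np.where(year_genes, rng_e.normal(0.0, 0.3, n_rows), 0.0)
    sex_eff[flat] = 0.0
    year_eff[flat] = 0.0

    de_sign = {}
    for t in config.tissues:
        for g in de_gene_ids[t]:
            de_sign[(g, t)] = 1 if rng_e.random() < 0.5 else -1

    factors = {reg: rng_e.normal(0.0, 1.0, n_anim) for reg in regulators}
    beta = {"high": _wiring_loading(config.wiring_r_high, config.noise_sd),
            "low": _wiring_loading(config.wiring_r_low, config.noise_sd)}
    grp_vec = np.array([groups[a] for a in animals])
    is_male = np.array([a in set(males) for a in animals], dtype=float)
    year_vec = np.array([years[a] - 1 for a in animals], dtype=float)
    high_mask = (grp_vec == "high").astype(float)

    log2_latent: dict[str, np.ndarray] = {}
    for tcol, t in enumerate(config.tissues):
        eps = rng_e.normal(0.0, config.noise_sd, size=(n_rows, n_anim))
        mat = (baseline[:, None] + tissue_off[:, [tcol]]
               + np.outer(sex_eff, is_male) + np.outer(year_eff, year_vec)
               + eps)
        for g in de_gene_ids[t]:
            shift = de_sign[(g, t)] * config.de_effect_log2fc / 2.0
            mat[idx[g], :] += np.where(high_mask == 1.0, shift, -shift)
        for reg in regulators:
            f = factors[reg]
            ri = idx[reg]
            mat[ri, :] = (baseline[ri] + f + 0.2 * eps[ri, :]
                          + sex_eff[ri] * is_male + year_eff[ri] * year_vec)
            b = np.where(high_mask == 1.0, beta["high"], beta["low"])
            for g in target_map[reg]:
                gi = idx[g]
                mat[gi, :] = (baseline[gi] + b * f + eps[gi, :]
                              + sex_eff[gi] * is_male + year_eff[gi] * year_vec)
                if (g, t) in de_sign:
                    shift = de_sign[(g, t)] * config.de_effect_log2fc / 2.0
                    mat[gi, :] += np.where(high_mask == 1.0, shift, -shift)
        log2_latent[t] = mat

    # ---- counts --------------------------------------------------------
    rng_c = _rng(seed, "counts")
    lengths = gene_table.set_index("gene_id")["length"].loc[all_genes].to_numpy(float)
    counts = {}
    for t in config.tissues:
        lib = rng_c.uniform(40e6, 55e6, size=n_anim)
        fpkm = np.power(2.0, log2_latent[t])
        mean = fpkm * (lengths[:, None] / 1000.0) * (lib[None, :] / 1e6)
        counts[t] = pd.DataFrame(rng_c.poisson(mean), index=all_genes, columns=animals)

    # ---- phenotypes ----------------------------------------------------
    population = PopulationStats(rfi_mean=0.0, rfi_sd=14.0, adg_mean=1.2, adg_sd=0.2,
                                 cfc_cow_mean=21.8, cfc_cow_sd=5.3)
    phenotypes = _simulate_phenotypes(config, _rng(seed, "phenotypes"),
                                      animals, males, groups, years)

    # ---- metabolites ---------------------------------------------------
    rng_m = _rng(seed, "metabolites")
    met_ids = [f"MET{i + 1:04d}" for i in range(config.n_metabolites)]
    met = 10.0 + rng_m.normal(0.0, 1.0, size=(config.n_metabolites, n_anim))
    links: dict[str, list[tuple[str, int]]] = {reg: [] for reg in regulators}
    best_tissue: dict[str, str] = {}
    gamma = config.metabolite_link_r / np.sqrt(1 - config.metabolite_link_r**2)
    mi = 0
    for reg in regulators:
        means = {t: float(np.mean(log2_latent[t][idx[reg], :])) for t in config.tissues}
        best_tissue[reg] = max(config.tissues, key=lambda t: means[t])
        z = log2_latent[best_tissue[reg]][idx[reg], :]
        z = (z - z.mean()) / z.std()
        for k in range(2):
            sign = 1 if k % 2 == 0 else -1
            met[mi, :] = 10.0 + sign * gamma * z + rng_m.normal(0.0, 1.0, n_anim)
            links[reg].append((met_ids[mi], sign))
            mi += 1
    missing = _rng(seed, "missing").random(met.shape) < config.metabolite_missing_rate
    met = np.where(missing, np.nan, met)
    metabolites = pd.DataFrame(met, index=met_ids, columns=animals)

    # ---- QTL -----------------------------------------------------------
    # planted targets enter the prioritized set through QTL overlap (a
    # category without expression consequences, so the planted wiring
    # correlation is not perturbed); extra random intervals on top
    qtl = _simulate_qtl(config, _rng(seed, "qtl"), gene_table,
                        cover=[g for ts in target_map.values() for g in ts])
    qtl_flags = flag_qtl_overlap(gene_table, qtl)
    qtl_gene_ids = {trait: sorted(qtl_flags.index[qtl_flags[trait]])
                    for trait in qtl_flags.columns}

    ground_truth = GroundTruth(
        planted_regulator_ids=list(regulators),
        target_map=target_map,
        de_gene_ids={t: sorted(v) for t, v in de_gene_ids.items()},
        ts_gene_ids={t: sorted(v) for t, v in ts_gene_ids.items()},
        qtl_gene_ids=qtl_gene_ids,
        lncrna_ids=list(lnc_ids),
        decoy_ids=list(decoy_ids),
        isolated_lnc_ids=gt_classes["isolated"],
        genic_lnc_ids=gt_classes["genic"],
        metabolite_links=links,
        regulator_best_tissue=best_tissue,
    )
    return SyntheticDataset(
        config=config, counts=counts, annotation=models, gene_table=gene_table,
        phenotypes=phenotypes, population=population, metabolites=metabolites,
        qtl=qtl, ground_truth=ground_truth,
    )


def _simulate_phenotypes(cfg, rng, animals, males, groups, years) -> pd.DataFrame:
    male_set = set(males)
    # Bulls are simulated as efficiency-contrast pairs matched on growth and
    # body weight: a pair shares ADG and weights and carries equal, opposite
    # planted RFI. The planted vector is then exactly orthogonal to the
    # intake regression design (intercept + ADG + MMW) and the realized OLS
    # residuals reproduce it; with unmatched covariates, n=24 bulls leave
    # the ADG slope weakly identified and the fit soaks up part of the
    # planted separation.
    high_bulls = [a for a in males if groups[a] == "high"]
    low_bulls = [a for a in males if groups[a] == "low"]
    pair_traits: dict[str, dict] = {}
    for hb, lb in zip(high_bulls, low_bulls):
        shared = {"adg": _trunc_normal(rng, 1.25, 0.12, lo=1.05),
                  "w17": rng.normal(600.0, 40.0)}
        shared["w18"] = shared["w17"] + rng.normal(25.0, 5.0)
        mag = _trunc_normal(rng, 21.0, 4.4, lo=16.0)
        pair_traits[hb] = {**shared, "rfi_planted": -mag}
        pair_traits[lb] = {**shared, "rfi_planted": +mag}
    for a in high_bulls[len(low_bulls):] + low_bulls[len(high_bulls):]:
        pair_traits[a] = {"adg": _trunc_normal(rng, 1.25, 0.12, lo=1.05),
                          "w17": rng.normal(600.0, 40.0),
                          "w18": rng.normal(625.0, 40.0),
                          "rfi_planted": 0.0}  # unmatched bull sits mid-band

    rows = []
    for a in animals:
        high = groups[a] == "high"
        rec = {"animal_id": a, "sex": "male" if a in male_set else "female",
               "group_true": groups[a], "year": years[a]}
        if a in male_set:
            tr = pair_traits[a]
            rec.update(adg=tr["adg"], weight_m17=tr["w17"], weight_m18=tr["w18"],
                       rfi_planted=tr["rfi_planted"])
            rec["imf"] = (_trunc_normal(rng, 1.71, 1.00, lo=0.2) if high
                          else _trunc_normal(rng, 4.64, 1.84, lo=0.5))
            rec["cfc"] = (_trunc_normal(rng, 14.2, 3.0, lo=5.0) if high
                          else _trunc_normal(rng, 20.2, 4.4, lo=10.0))
            rec.update(milk_yield_7d=np.nan, fat_pct=np.nan, protein_pct=np.nan,
                       ecm_w=np.nan, calving_interval=np.nan,
                       age_at_slaughter=float(rng.integers(530, 560)))
        else:
            fat = _trunc_normal(rng, 4.0, 0.3, lo=3.0)
            prot = _trunc_normal(rng, 3.4, 0.15, lo=3.0)
            ecm = (_trunc_normal(rng, 190.87, 22.02, lo=150.0) if high
                   else _trunc_normal(rng, 30.97, 9.18, lo=15.0, hi=40.0))
            my = ecm * 3.1 / (0.37 * fat + 0.21 * prot + 0.95)
            rec.update(
                milk_yield_7d=my, fat_pct=fat, protein_pct=prot,
                ecm_w=compute_ecm(fat, prot, my),
                cfc=(_trunc_normal(rng, 17.1, 2.7, lo=8.0, hi=26.0) if high
                     else _trunc_normal(rng, 25.9, 3.6, lo=17.5)),
                imf=(_trunc_normal(rng, 4.16, 1.60, lo=1.0) if high
                     else _trunc_normal(rng, 6.46, 2.53, lo=1.0)),
                calving_interval=float(rng.integers(360, 500)),
                age_at_slaughter=float(rng.integers(1250, 1500)),
                adg=np.nan, weight_m17=np.nan, weight_m18=np.nan, energy_intake=np.nan,
            )
        rec["pathology_flag"] = False
        rows.append(rec)
    df = pd.DataFrame(rows)
    bulls = df["sex"] == "male"
    mmw = metabolic_midweight(df.loc[bulls, "weight_m17"], df.loc[bulls, "weight_m18"])
    df.loc[bulls, "energy_intake"] = 500.0 + 40.0 * df.loc[bulls, "adg"] \
        + 1.2 * np.asarray(mmw) + df.loc[bulls, "rfi_planted"]
    df = df.drop(columns="rfi_planted")
    df["rfi"] = np.nan
    df.loc[bulls, "rfi"] = compute_rfi(df.loc[bulls, "energy_intake"],
                                       df.loc[bulls, "adg"], mmw)
    cols = ["animal_id", "sex", "group_true", "year", "milk_yield_7d", "fat_pct",
            "protein_pct", "ecm_w", "energy_intake", "adg", "weight_m17", "weight_m18",
            "rfi", "imf", "cfc", "calving_interval", "age_at_slaughter", "pathology_flag"]
    return df[cols]


def _simulate_qtl(cfg, rng, gene_table, cover: list[str] = ()) -> list[QTLInterval]:
    coding = gene_table[gene_table["biotype"] == "protein_coding"].reset_index(drop=True)
    qtl = []
    span = gene_table.set_index("gene_id")
    for i, g in enumerate(cover):
        row = span.loc[g]
        qtl.append(QTLInterval(str(row["chrom"]),
                               max(1, int(row["start"]) - int(rng.integers(0, 2_000))),
                               int(row["end"]) + int(rng.integers(0, 2_000)),
                               "RFI" if i % 2 == 0 else "MY"))
    for i in range(cfg.n_qtl):
        trait = "RFI" if i % 2 == 0 else "MY"
        if i % 3 == 2:  # gene-desert interval (no overlap expected)
            start = int(rng.integers(1_000_000, 5_000_000))
            qtl.append(QTLInterval("5", start, start + int(rng.integers(5_000, 50_000)), trait))
        else:
            g = coding.iloc[int(rng.integers(0, len(coding)))]
            start = max(1, int(g["start"]) - int(rng.integers(0, 5_000)))
            end = int(g["end"]) + int(rng.integers(0, 5_000))
            qtl.append(QTLInterval(str(g["chrom"]), start, end, trait))
    return qtl


# ---------------------------------------------------------------------------
# on-disk round trip
# ---------------------------------------------------------------------------

def write_dataset(ds: SyntheticDataset, out_dir: str | Path) -> dict[str, str]:
    """Write the dataset as plain-text files; returns a name -> path manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}

    for tissue, block in ds.counts.items():
        name = f"counts_{tissue}.tsv"
        block.rename_axis("gene_id").to_csv(out / name, sep="\t")
        manifest[f"counts:{tissue}"] = name
    write_gtf(ds.annotation, out / "annotation.gtf")
    manifest["annotation"] = "annotation.gtf"
    ds.phenotypes.to_csv(out / "phenotypes.tsv", sep="\t", index=False, float_format="%.6g")
    manifest["phenotypes"] = "phenotypes.tsv"
    pop = ds.population
    pd.DataFrame(
        {"stat": ["rfi_mean", "rfi_sd", "adg_mean", "adg_sd", "cfc_cow_mean", "cfc_cow_sd"],
         "value": [pop.rfi_mean, pop.rfi_sd, pop.adg_mean, pop.adg_sd,
                   pop.cfc_cow_mean, pop.cfc_cow_sd]}
    ).to_csv(out / "population_stats.tsv", sep="\t", index=False, float_format="%.6g")
    manifest["population_stats"] = "population_stats.tsv"
    ds.metabolites.rename_axis("metabolite_id").to_csv(
        out / "metabolites.tsv", sep="\t", float_format="%.6g")
    manifest["metabolites"] = "metabolites.tsv"
    write_bed(ds.qtl, out / "qtl.bed")
    manifest["qtl"] = "qtl.bed"
    _write_ground_truth(ds.ground_truth, out / "ground_truth.tsv")
    manifest["ground_truth"] = "ground_truth.tsv"
    _write_gmt(ds, out / "pathways.gmt")
    manifest["pathways"] = "pathways.gmt"
    ds.config.to_yaml(out / "config.yaml")
    manifest["config"] = "config.yaml"

    with open(out / "MANIFEST.tsv", "w") as fh:
        for key in sorted(manifest):
            fh.write(f"{key}\t{manifest[key]}\n")
    return manifest


def _write_ground_truth(gt: GroundTruth, path: Path) -> None:
    rows = []
    for reg in gt.planted_regulator_ids:
        rows.append(("planted_regulator", reg, gt.regulator_best_tissue[reg]))
        rows += [("target", reg, g) for g in gt.target_map[reg]]
        rows += [("metabolite_link", reg, f"{m}:{s:+d}") for m, s in gt.metabolite_links[reg]]
    for t, genes in gt.de_gene_ids.items():
        rows += [("de", t, g) for g in genes]
    for t, genes in gt.ts_gene_ids.items():
        rows += [("ts", t, g) for g in genes]
    for trait, genes in gt.qtl_gene_ids.items():
        rows += [("qtl", trait, g) for g in genes]
    rows += [("lncrna", "", g) for g in gt.lncrna_ids]
    rows += [("decoy", "", g) for g in gt.decoy_ids]
    rows += [("isolated_lnc", "", g) for g in gt.isolated_lnc_ids]
    rows += [("genic_lnc", "", g) for g in gt.genic_lnc_ids]
    pd.DataFrame(rows, columns=["section", "key", "value"]).to_csv(path, sep="\t", index=False)


def read_ground_truth(path: str | Path) -> GroundTruth:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    sec = {s: g for s, g in df.groupby("section")}

    def _pairs(name):
        out: dict[str, list[str]] = {}
        for _, r in sec.get(name, pd.DataFrame(columns=df.columns)).iterrows():
            out.setdefault(r["key"], []).append(r["value"])
        return out

    regs = list(sec.get("planted_regulator", pd.DataFrame(columns=df.columns))["key"])
    best = dict(zip(sec["planted_regulator"]["key"], sec["planted_regulator"]["value"])) \
        if "planted_regulator" in sec else {}
    links = {}
    for reg, vals in _pairs("metabolite_link").items():
        links[reg] = [(v.rsplit(":", 1)[0], int(v.rsplit(":", 1)[1])) for v in vals]
    return GroundTruth(
        planted_regulator_ids=regs,
        target_map=_pairs("target"),
        de_gene_ids=_pairs("de"),
        ts_gene_ids=_pairs("ts"),
        qtl_gene_ids=_pairs("qtl"),
        lncrna_ids=list(sec.get("lncrna", pd.DataFrame(columns=df.columns))["value"]),
        decoy_ids=list(sec.get("decoy", pd.DataFrame(columns=df.columns))["value"]),
        isolated_lnc_ids=list(sec.get("isolated_lnc", pd.DataFrame(columns=df.columns))["value"]),
        genic_lnc_ids=list(sec.get("genic_lnc", pd.DataFrame(columns=df.columns))["value"]),
        metabolite_links=links,
        regulator_best_tissue=best,
    )


def _write_gmt(ds: SyntheticDataset, path: Path) -> None:
    """Planted modules (genes + linked metabolites) plus random control sets."""
    gt = ds.ground_truth
    rng = _rng(ds.config.seed, "qtl")  # reuse a fixed stream for the control sets
    coding = [g for g in ds.gene_table["gene_id"]
              if g.startswith("GENE")]
    with open(path, "w") as fh:
        for reg in gt.planted_regulator_ids:
            members = [f"gene:{g}" for g in gt.target_map[reg]]
            members += [f"met:{m}" for m, _ in gt.metabolite_links[reg]]
            fh.write("\t".join([f"MODULE_{reg}", f"planted targets of {reg}", *members]) + "\n")
        for k in range(5):
            size = int(rng.integers(15, 40))
            members = [f"gene:{g}" for g in rng.choice(coding, size=size, replace=False)]
            fh.write("\t".join([f"RANDOM_{k + 1}", "random control set", *members]) + "\n")


def read_counts(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_metabolites(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
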