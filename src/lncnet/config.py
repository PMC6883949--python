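"""Simulation configuration for the synthetic cohort generator."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

#: Tissues sampled in the emulated study design.
DEFAULT_TISSUES = ("jejunum", "liver", "muscle", "rumen")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Defaults mirror the emulated study design: 48 animals (24 per sex) in a
    high group of 25 (12 males / 13 females) and a low group of 23
    (12 males / 11 females), four metabolic tissues, differential expression
    in three of the four tissues (none in rumen), lncRNAs drawn
    systematically lower-expressed than mRNAs, planted regulators whose
    correlation to their target module differs between the groups
    (``wiring_r_high`` vs ``wiring_r_low``), and 640 plasma metabolites with
    below-detection missingness.
    """

    n_animals: int = 48
    n_per_sex: int = 24
    group_sizes: tuple[int, int] = (25, 23)  # (high, low)
    tissues: tuple[str, ...] = DEFAULT_TISSUES
    n_genes: int = 1000
    n_lncrna: int = 200
    n_planted_regulators: int = 4
    targets_per_regulator: int = 30
    wiring_r_high: float = 0.8
    wiring_r_low: float = 0.0
    de_effect_log2fc: float = 1.0
    noise_sd: float = 0.5  # log2-FPKM units
    n_metabolites: int = 640
    metabolite_missing_rate: float = 0.08
    metabolite_link_r: float = 0.4  # true |r| of planted metabolite links
    n_de_per_tissue: int = 60  # extra (non-module) DE genes per DE tissue
    n_ts_per_tissue: int = 25
    n_qtl: int = 30
    seed: int = 7

    def validate(self) -> None:
        if self.n_animals <= 0 or self.n_genes <= 0 or len(self.tissues) == 0:
            raise ValueError("dimensions must be positive")
        if sum(self.group_sizes) != self.n_animals:
            raise ValueError(
                f"group sizes {self.group_sizes} do not sum to n_animals={self.n_animals}"
            )
        if self.n_per_sex * 2 != self.n_animals:
            raise ValueError("n_per_sex must be half of n_animals")
        if abs(self.wiring_r_high) > 1 or abs(self.wiring_r_low) > 1:
            raise ValueError("wiring correlations must lie in [-1, 1]")
        if self.n_lncrna > self.n_genes:
            raise ValueError("n_lncrna cannot exceed n_genes")
        if not 0 <= self.metabolite_missing_rate < 1:
            raise ValueError("metabolite_missing_rate must be in [0, 1)")
        n_targets = self.n_planted_regulators * self.targets_per_regulator
        n_mrna = self.n_genes - self.n_lncrna
        if n_targets + 3 * self.n_de_per_tissue + len(self.tissues) * self.n_ts_per_tissue > n_mrna:
            raise ValueError("not enough mRNA genes for the requested planted structure")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "group_sizes" in raw:
            raw["group_sizes"] = tuple(raw["group_sizes"])
        if "tissues" in raw:
            raw["tissues"] = tuple(raw["tissues"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        raw = asdict(self)
        raw["group_sizes"] = list(self.group_sizes)
        raw["tissues"] = list(self.tissues)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True)
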