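"""Simulation configuration for the synthetic RRBS + RNA-seq generator."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Tuple

import yaml


@dataclass
class SimulationConfig:
    """Parameters of the synthetic two-group study.

    The defaults emulate the structure of a parental-diet liver study:
    a 6-vs-6 RRBS design and a 4-vs-4 expression design, a strongly
    bimodal methylome (80% of CpGs above 0.8 methylation, 6% below
    0.1), a methylation dip with elevated RRBS coverage at CpG-island
    promoters, planted differentially methylated CpGs near promoters
    and a predominantly down-regulated planted gene module.

    Parameters
    ----------
    n_samples_per_group : samples per feed group in the RRBS design.
    n_samples_per_group_expr : samples per group in the expression design.
    coverage_mean : mean total read count per CpG per sample outside
        CpG islands; boosted by ``coverage_island_boost`` inside islands.
    fraction_high, fraction_low : target genome-wide fractions of CpGs
        whose mean methylation lies above 0.8 / below 0.1.
    beta_high, beta_low, beta_mid : (a, b) shapes of the Beta mixture
        components for highly / lowly / intermediately methylated sites.
    n_true_dml : number of CpGs carrying a planted group difference.
    delta_beta : planted methylation difference (proportion scale).
    dml_cluster_size : consecutive CpGs per planted cluster (1 = isolated
        loci; larger values create region-scale signals).
    dispersion : beta-binomial dispersion phi of replicate methylation.
    n_true_deg : number of planted differentially expressed genes.
    deg_log2fc : |log2 fold change| of planted genes.
    fraction_deg_down : probability a planted gene is down-regulated in
        the treatment group.
    expr_cv : lognormal coefficient of variation of replicate abundances.
    tss_band_shift : optional group-wide methylation shift planted in
        the strand-oriented upstream distance band ``tss_band`` (used to
        emulate a promoter-confined group signal; 0 disables it).
    """

    n_samples_per_group: int = 6
    n_samples_per_group_expr: int = 4
    coverage_mean: float = 30.0
    coverage_nb_size: float = 5.0
    coverage_island_boost: float = 3.0

    fraction_high: float = 0.80
    fraction_low: float = 0.06
    beta_high: Tuple[float, float] = (30.0, 2.0)
    beta_low: Tuple[float, float] = (0.8, 25.0)
    beta_mid: Tuple[float, float] = (2.0, 2.0)
    dispersion: float = 0.01

    n_true_dml: int = 100
    delta_beta: float = 0.3
    dml_cluster_size: int = 1

    n_true_deg: int = 100
    deg_log2fc: float = 2.0
    fraction_deg_down: float = 0.68
    expr_cv: float = 0.2
    expr_log2_mean: float = 5.0
    expr_log2_sd: float = 2.0

    # annotation geometry
    n_chroms: int = 2
    chrom_length: int = 4_000_000
    n_transcripts: int = 400
    n_islands: int = 250
    island_tss_fraction: float = 0.7
    island_length_mean: int = 800
    background_cpg_spacing: float = 150.0
    island_cpg_spacing: float = 30.0
    gene_region_fraction: float = 0.6

    tss_dip_halfwidth: int = 200
    tss_band_shift: float = 0.0
    tss_band: Tuple[int, int] = (1600, 4800)

    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("fraction_high", "fraction_low", "fraction_deg_down",
                     "island_tss_fraction", "gene_region_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must lie in [0, 1]")
        if self.fraction_high + self.fraction_low > 1.0:
            raise ValueError("mixture fractions exceed 1")
        if self.coverage_mean <= 0:
            raise ValueError("coverage_mean must be positive")
        if not 0.0 <= self.dispersion < 1.0:
            raise ValueError("dispersion must lie in [0, 1)")
        if abs(self.delta_beta) >= 1.0:
            raise ValueError("delta_beta must keep group means in [0, 1]")
        if self.n_chroms < 1 or self.n_transcripts < 1:
            raise ValueError("need at least one chromosome and one transcript")
        if self.n_samples_per_group < 1 or self.n_samples_per_group_expr < 1:
            raise ValueError("need at least one sample per group")

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["beta_high"] = list(d["beta_high"])
        d["beta_low"] = list(d["beta_low"])
        d["beta_mid"] = list(d["beta_mid"])
        d["tss_band"] = list(d["tss_band"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        for key in ("beta_high", "beta_low", "beta_mid", "tss_band"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)
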