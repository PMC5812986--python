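"""Synthetic genome annotation, RRBS methylome and expression generator.

Everything downstream is validated against the ground truth planted
here: a compact two-chromosome annotation with CpG-island promoters, a
bimodal beta-mixture methylome with a methylation dip and an RRBS
coverage peak at TSSs, planted differentially methylated CpGs near
promoters, and a predominantly down-regulated planted gene module.

A single global seed governs all draws; each stage derives its own
sub-stream so the stages stay decoupled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .expression import ExpressionTable
from .methylation import MethylationTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Transcript:
    transcript_id: str
    chrom: str
    start: int
    end: int
    strand: str
    tss: int
    exons: Tuple[Tuple[int, int], ...]


@dataclass
class GenomeModel:
    """Chromosomes, transcripts with exons, CpG islands and CpG sites."""

    chrom_sizes: Dict[str, int]
    transcripts: List[Transcript]
    cpg_islands: List[Tuple[str, int, int]]
    cpg_chrom: np.ndarray
    cpg_pos: np.ndarray

    def __post_init__(self) -> None:
        self.cpg_chrom = np.asarray(self.cpg_chrom)
        self.cpg_pos = np.asarray(self.cpg_pos, dtype=np.int64)
        self.validate()

    def validate(self) -> None:
        for t in self.transcripts:
            L = self.chrom_sizes[t.chrom]
            if not (0 <= t.start < t.end <= L):
                raise ValueError(f"{t.transcript_id} outside chromosome bounds")
            expected_tss = t.start if t.strand == "+" else t.end
            if t.tss != expected_tss:
                raise ValueError(f"{t.transcript_id} TSS must sit at the "
                                 "transcript boundary for its strand")
            for es, ee in t.exons:
                if not (t.start <= es < ee <= t.end):
                    raise ValueError(f"exon outside {t.transcript_id}")
        for c, s, e in self.cpg_islands:
            if not (0 <= s < e <= self.chrom_sizes[c]):
                raise ValueError("island outside chromosome bounds")
        for c in self.chrom_sizes:
            p = self.cpg_pos[self.cpg_chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"CpG positions not strictly increasing on {c}")

    @property
    def n_sites(self) -> int:
        return len(self.cpg_pos)

    def tss_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(t.chrom, t.tss, t.strand, t.transcript_id) for t in self.transcripts],
            columns=["chrom", "tss", "strand", "transcript_id"],
        )


@dataclass
class TruthSet:
    """Planted effects: DML sites with signed deltas, DEGs with signed
    log2 fold changes."""

    dml: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["chrom", "pos", "delta"])
    )
    deg: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["gene_id", "log2fc"])
    )


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed) % (2**31), stream])


# ---------------------------------------------------------------------------
# annotation


def simulate_annotation(config: SimulationConfig) -> GenomeModel:
    """Generate a compact annotation with island-rich promoters.

    Genes occupy the first ``gene_region_fraction`` of every chromosome
    (leaving gene deserts that provide intergenic space); a Bernoulli
    ``island_tss_fraction`` of CpG islands sit centred on TSSs and the
    rest fall uniformly.  CpG density is elevated inside islands
    (spacing ``island_cpg_spacing`` vs ``background_cpg_spacing``).
    """
    config.validate()
    rng = _rng(config, 1)
    chroms = [f"chr{i + 1}" for i in range(config.n_chroms)]
    chrom_sizes = {c: int(config.chrom_length) for c in chroms}

    # transcripts on a jittered grid inside the gene-rich region
    per_chrom = np.array_split(np.arange(config.n_transcripts), config.n_chroms)
    transcripts: List[Transcript] = []
    for c, idxs in zip(chroms, per_chrom):
        if len(idxs) == 0:
            continue
        region = int(config.chrom_length * config.gene_region_fraction)
        slot = region // max(len(idxs), 1)
        for j, gi in enumerate(idxs):
            length = int(rng.integers(2000, min(20000, max(4000, slot - 200))))
            lo = j * slot + 100
            hi = max(lo + 1, (j + 1) * slot - length - 100)
            start = int(rng.integers(lo, hi))
            end = min(start + length, chrom_sizes[c])
            strand = "+" if rng.random() < 0.5 else "-"
            n_exons = int(rng.integers(2, 8))
            cuts = np.sort(rng.choice(np.arange(start + 1, end), size=2 * n_exons - 2,
                                      replace=False)) if end - start > 2 * n_exons else np.array([], int)
            bounds = np.concatenate([[start], cuts, [end]])
            exons = tuple(
                (int(bounds[2 * i]), int(bounds[2 * i + 1]))
                for i in range(len(bounds) // 2)
            )
            tss = start if strand == "+" else end
            transcripts.append(Transcript(f"gene{gi:05d}", c, start, end,
                                          strand, tss, exons))
    if not transcripts:
        raise ValueError("no transcripts generated")

    # CpG islands: a Bernoulli fraction centred on distinct TSSs
    islands: List[Tuple[str, int, int]] = []
    tss_hits = rng.random(config.n_islands) < config.island_tss_fraction
    tss_choices = rng.choice(len(transcripts),
                             size=min(config.n_islands, len(transcripts)),
                             replace=False)
    ti = 0
    for i in range(config.n_islands):
        length = max(200, int(rng.normal(config.island_length_mean,
                                         config.island_length_mean / 4)))
        if tss_hits[i] and ti < len(tss_choices):
            t = transcripts[tss_choices[ti]]
            ti += 1
            centre = t.tss
            c = t.chrom
        else:
            c = chroms[int(rng.integers(len(chroms)))]
            centre = int(rng.integers(length, chrom_sizes[c] - length))
        s = max(0, centre - length // 2)
        e = min(chrom_sizes[c], s + length)
        islands.append((c, int(s), int(e)))

    # CpG sites: exponential gaps, denser inside islands
    all_chrom: List[str] = []
    all_pos: List[np.ndarray] = []
    for c in chroms:
        pos = _chromosome_cpgs(rng, chrom_sizes[c],
                               [(s, e) for ic, s, e in islands if ic == c],
                               config.background_cpg_spacing,
                               config.island_cpg_spacing)
        all_chrom.extend([c] * len(pos))
        all_pos.append(pos)
    cpg_pos = np.concatenate(all_pos) if all_pos else np.empty(0, np.int64)
    return GenomeModel(chrom_sizes, transcripts, islands,
                       np.asarray(all_chrom), cpg_pos)


def _chromosome_cpgs(rng, length, islands, bg_spacing, island_spacing):
    """Background CpGs at mean ``bg_spacing``, extra island CpGs at
    ``island_spacing``, merged, deduplicated and sorted."""
    n_bg = int(length / bg_spacing * 1.2) + 10
    gaps = rng.exponential(bg_spacing, size=n_bg).astype(np.int64) + 1
    bg = np.cumsum(gaps)
    bg = bg[bg < length]
    parts = [bg]
    for s, e in islands:
        n_isl = int((e - s) / island_spacing * 1.5) + 2
        g = rng.exponential(island_spacing, size=n_isl).astype(np.int64) + 1
        p = s + np.cumsum(g)
        parts.append(p[p < e])
    return np.unique(np.concatenate(parts))


# ---------------------------------------------------------------------------
# methylome


def simulate_methylome(
    model: GenomeModel, config: SimulationConfig
) -> Tuple[MethylationTable, TruthSet]:
    """Beta-binomial RRBS counts over the model's CpG sites.

    Latent per-site methylation comes from a three-component Beta
    mixture.  Sites within ``tss_dip_halfwidth`` of a TSS draw from the
    low component (the TSS dip); background component probabilities are
    solved so the *net* genome-wide high/low fractions match the
    configured profile whatever the annotation geometry.  Coverage is
    negative-binomial, boosted inside islands.  Exactly ``n_true_dml``
    sites (in clusters of ``dml_cluster_size`` consecutive CpGs, placed
    within promoters where possible) carry a signed group difference of
    ``delta_beta``.
    """
    from .context import positions_in_intervals, merge_intervals

    config.validate()
    rng = _rng(config, 2)
    n_sites = model.n_sites
    n_per = config.n_samples_per_group
    samples = [f"ctrl{i + 1}" for i in range(n_per)] + \
              [f"low1C{i + 1}" for i in range(n_per)]
    groups = {s: ("control" if s.startswith("ctrl") else "low1C") for s in samples}

    near_tss = _near_tss_mask(model, config.tss_dip_halfwidth)
    f_t = near_tss.mean() if n_sites else 0.0

    # net-profile solve: near-TSS sites are 'low'; background component
    # probabilities are chosen so genome-wide fractions hit the config
    p_high_bg = min(1.0, config.fraction_high / max(1.0 - f_t, 1e-9))
    p_low_bg = min(1.0 - p_high_bg,
                   max(0.0, (config.fraction_low - f_t) / max(1.0 - f_t, 1e-9)))
    p_mid_bg = max(0.0, 1.0 - p_high_bg - p_low_bg)

    comp = np.full(n_sites, 2)  # 0=high, 1=low, 2=mid
    u = rng.random(n_sites)
    comp[u < p_high_bg] = 0
    comp[(u >= p_high_bg) & (u < p_high_bg + p_low_bg)] = 1
    comp[near_tss] = 1

    latent = np.empty(n_sites)
    for ci, (a, b) in enumerate([config.beta_high, config.beta_low, config.beta_mid]):
        sel = comp == ci
        latent[sel] = rng.beta(a, b, size=int(sel.sum()))
    latent = np.clip(latent, 1e-4, 1 - 1e-4)

    # planted DMLs, preferentially inside promoters, clustered
    truth_dml = _plant_dml(model, config, rng, latent)

    # per-group latent levels
    delta = np.zeros(n_sites)
    if len(truth_dml):
        delta[truth_dml.index.to_numpy()] = truth_dml["delta"].to_numpy()
    band_shift = _upstream_band_shift(model, config)
    latent_ctrl = latent
    latent_trt = np.clip(latent + delta + band_shift, 1e-4, 1 - 1e-4)

    # coverage: negative binomial, boosted inside islands
    isl_by_chrom: Dict[str, np.ndarray] = {}
    for c in model.chrom_sizes:
        iv = [(s, e) for ic, s, e in model.cpg_islands if ic == c]
        isl_by_chrom[c] = merge_intervals(np.asarray(iv, np.int64).reshape(-1, 2))
    in_island = np.zeros(n_sites, bool)
    for c in model.chrom_sizes:
        sel = model.cpg_chrom == c
        in_island[sel] = positions_in_intervals(model.cpg_pos[sel], isl_by_chrom[c])
    mean_cov = np.where(in_island,
                        config.coverage_mean * config.coverage_island_boost,
                        config.coverage_mean)
    size = config.coverage_nb_size
    t = rng.negative_binomial(size, size / (size + mean_cov),
                              size=(2 * n_per, n_sites))

    # beta-binomial counts: per-sample success probability around the
    # group latent with dispersion phi
    phi = config.dispersion
    m = np.empty_like(t)
    for si in range(2 * n_per):
        lat = latent_ctrl if si < n_per else latent_trt
        if phi > 0:
            conc = (1.0 - phi) / phi
            p_s = rng.beta(lat * conc, (1.0 - lat) * conc)
        else:
            p_s = lat
        m[si] = rng.binomial(t[si], p_s)

    table = MethylationTable(
        chrom=model.cpg_chrom, pos=model.cpg_pos, m=m, t=t,
        samples=samples, groups=groups,
    )
    truth = TruthSet(
        dml=pd.DataFrame(
            {
                "chrom": model.cpg_chrom[truth_dml.index.to_numpy()],
                "pos": model.cpg_pos[truth_dml.index.to_numpy()],
                "delta": truth_dml["delta"].to_numpy(),
            }
        )
        if len(truth_dml)
        else pd.DataFrame(columns=["chrom", "pos", "delta"]),
    )
    return table, truth


def _near_tss_mask(model: GenomeModel, halfwidth: int) -> np.ndarray:
    mask = np.zeros(model.n_sites, bool)
    tss_by_chrom: Dict[str, List[int]] = {}
    for t in model.transcripts:
        tss_by_chrom.setdefault(t.chrom, []).append(t.tss)
    for c, tlist in tss_by_chrom.items():
        tpos = np.sort(np.asarray(tlist, np.int64))
        sel = np.where(model.cpg_chrom == c)[0]
        if len(sel) == 0:
            continue
        p = model.cpg_pos[sel]
        right = np.searchsorted(tpos, p)
        left = np.clip(right - 1, 0, len(tpos) - 1)
        right = np.clip(right, 0, len(tpos) - 1)
        d = np.minimum(np.abs(p - tpos[left]), np.abs(p - tpos[right]))
        mask[sel] = d <= halfwidth
    return mask


def _upstream_band_shift(model: GenomeModel, config: SimulationConfig) -> np.ndarray:
    """Optional planted treatment-group shift in an upstream TSS band."""
    if config.tss_band_shift == 0.0:
        return np.zeros(model.n_sites)
    from .context import signed_tss_distance

    d = signed_tss_distance(model.cpg_chrom, model.cpg_pos, model)
    lo, hi = config.tss_band
    in_band = (d <= -lo) & (d >= -hi)
    return np.where(in_band, config.tss_band_shift, 0.0)


def _plant_dml(model, config, rng, latent) -> pd.DataFrame:
    """Pick DML site indices (clustered, promoter-preferring) and signed
    deltas feasible for their latent levels; infeasible picks are
    resampled and logged."""
    n = config.n_true_dml
    if n == 0:
        return pd.DataFrame(columns=["delta"])
    from .context import positions_in_intervals, merge_intervals

    # candidate anchors: CpGs inside strand-aware promoters
    promoter = {c: [] for c in model.chrom_sizes}
    for t in model.transcripts:
        if t.strand == "+":
            promoter[t.chrom].append([max(0, t.tss - 5000), t.tss])
        else:
            promoter[t.chrom].append([t.tss, t.tss + 5000])
    cand = np.zeros(model.n_sites, bool)
    for c in model.chrom_sizes:
        sel = model.cpg_chrom == c
        iv = merge_intervals(np.asarray(promoter[c], np.int64).reshape(-1, 2))
        cand[sel] = positions_in_intervals(model.cpg_pos[sel], iv)
    cand_idx = np.where(cand)[0]
    if len(cand_idx) < n:
        cand_idx = np.arange(model.n_sites)

    k = max(1, int(config.dml_cluster_size))
    n_clusters = int(np.ceil(n / k))
    chosen: List[int] = []
    taken = set()
    anchors = rng.permutation(cand_idx)
    ai = 0
    delta_mag = abs(config.delta_beta)
    deltas: List[float] = []
    while len(chosen) < n and ai < len(anchors):
        a = int(anchors[ai])
        ai += 1
        run = [a + j for j in range(k)
               if a + j < model.n_sites and model.cpg_chrom[a + j] == model.cpg_chrom[a]]
        if any(i in taken for i in run):
            continue
        sign = 1.0 if rng.random() < 0.5 else -1.0
        for i in run:
            if len(chosen) >= n:
                break
            d = sign * delta_mag
            if not 0.0 < latent[i] + d < 1.0:
                d = -d
            if not 0.0 < latent[i] + d < 1.0:
                logger.debug("site %d latent %.3f incompatible with delta; skipped",
                             i, latent[i])
                continue
            chosen.append(i)
            deltas.append(d)
            taken.add(i)
    if len(chosen) < n:
        logger.warning("planted only %d of %d requested DMLs", len(chosen), n)
    return pd.DataFrame({"delta": deltas}, index=pd.Index(chosen, name="site"))


# ---------------------------------------------------------------------------
# expression


def simulate_expression(
    model: GenomeModel, config: SimulationConfig
) -> Tuple[ExpressionTable, TruthSet]:
    """Log-normal FPKM-like abundances with planted signed DEGs.

    Baseline log2 abundances are Normal(expr_log2_mean, expr_log2_sd);
    replicates vary lognormally with coefficient of variation
    ``expr_cv``.  ``n_true_deg`` genes receive a ±``deg_log2fc`` shift
    in the treatment group, down-regulated with probability
    ``fraction_deg_down``.
    """
    config.validate()
    rng = _rng(config, 3)
    genes = [t.transcript_id for t in model.transcripts]
    if config.n_true_deg > len(genes):
        raise ValueError("n_true_deg exceeds the number of genes")
    n_per = config.n_samples_per_group_expr
    samples = [f"ctrl{i + 1}" for i in range(n_per)] + \
              [f"low1C{i + 1}" for i in range(n_per)]
    groups = {s: ("control" if s.startswith("ctrl") else "low1C") for s in samples}

    base_log2 = rng.normal(config.expr_log2_mean, config.expr_log2_sd, len(genes))
    deg_idx = rng.choice(len(genes), size=config.n_true_deg, replace=False)
    down = rng.random(config.n_true_deg) < config.fraction_deg_down
    signed_fc = np.where(down, -config.deg_log2fc, config.deg_log2fc)

    log2_mean = np.tile(base_log2[:, None], (1, 2 * n_per)).astype(float)
    log2_mean[deg_idx, n_per:] += signed_fc[:, None]
    sigma = np.sqrt(np.log1p(config.expr_cv**2))
    noise = rng.normal(0.0, sigma, size=log2_mean.shape)
    abundance = np.exp2(log2_mean) * np.exp(noise - sigma**2 / 2.0)

    table = ExpressionTable(
        pd.DataFrame(abundance, index=pd.Index(genes, name="gene_id"),
                     columns=samples),
        groups,
    )
    truth = TruthSet(
        deg=pd.DataFrame({"gene_id": [genes[i] for i in deg_idx],
                          "log2fc": signed_fc}),
    )
    return table, truth
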