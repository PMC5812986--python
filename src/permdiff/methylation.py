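"""Per-CpG differential methylation.

Coverage filtering, the between/within-group f-statistic track that
feeds the DMR caller, a beta-binomial Wald test with coverage-weighted
dispersion shrinkage (a re-specified DSS-style locus test), BH FDR and
genome-wide methylation summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

#: within-group-variance floor for the f-statistic; sites whose within
#: variance is exactly zero get f = 1/EPS_F and are excluded from mean_f
EPS_F = 1e-8


# ---------------------------------------------------------------------------
# containers


@dataclass
class MethylationTable:
    """Per-CpG methylated / total read counts for labelled samples.

    ``m`` and ``t`` are (n_samples, n_sites) integer arrays aligned to
    ``samples`` (rows) and to ``chrom``/``pos`` (columns).  Positions are
    0-based and strictly increasing within each chromosome.
    """

    chrom: np.ndarray
    pos: np.ndarray
    m: np.ndarray
    t: np.ndarray
    samples: List[str]
    groups: Dict[str, str]

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.m = np.asarray(self.m)
        self.t = np.asarray(self.t)
        self.validate()

    def validate(self) -> None:
        n_samples, n_sites = self.m.shape
        if self.t.shape != (n_samples, n_sites):
            raise ValueError("m and t shapes differ")
        if len(self.samples) != n_samples:
            raise ValueError("sample list does not match count matrix")
        if len(self.chrom) != n_sites or len(self.pos) != n_sites:
            raise ValueError("site arrays do not match count matrix")
        if np.any(self.m > self.t) or np.any(self.m < 0):
            raise ValueError("need 0 <= m <= t")
        for c in pd.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")
        labels = [self.groups[s] for s in self.samples]
        counts = pd.Series(labels).value_counts()
        if len(counts) != 2 or counts.min() < 1:
            raise ValueError("need samples from exactly two groups")

    @property
    def n_sites(self) -> int:
        return self.m.shape[1]

    @property
    def n_samples(self) -> int:
        return self.m.shape[0]

    @property
    def group_names(self) -> Tuple[str, str]:
        """The two group labels, ordered by first appearance in ``samples``."""
        seen: List[str] = []
        for s in self.samples:
            g = self.groups[s]
            if g not in seen:
                seen.append(g)
        return seen[0], seen[1]

    def group_indices(self) -> Tuple[np.ndarray, np.ndarray]:
        g1, g2 = self.group_names
        labels = np.array([self.groups[s] for s in self.samples])
        return np.where(labels == g1)[0], np.where(labels == g2)[0]

    def levels(self) -> np.ndarray:
        """Per-sample methylation proportions m/t (NaN where t == 0)."""
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.t > 0, self.m / np.maximum(self.t, 1), np.nan)

    def pooled_levels(self) -> np.ndarray:
        """Per-site mean methylation pooled over all samples' reads."""
        tot = self.t.sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(tot > 0, self.m.sum(axis=0) / np.maximum(tot, 1), np.nan)

    def subset_sites(self, mask: np.ndarray) -> "MethylationTable":
        return MethylationTable(
            chrom=self.chrom[mask],
            pos=self.pos[mask],
            m=self.m[:, mask],
            t=self.t[:, mask],
            samples=list(self.samples),
            groups=dict(self.groups),
        )

    def relabel(self, groups: Dict[str, str]) -> "MethylationTable":
        """Same counts under a different sample→group assignment."""
        return MethylationTable(self.chrom, self.pos, self.m, self.t,
                                list(self.samples), dict(groups))


@dataclass
class FStatTrack:
    """Per-retained-CpG f-statistics and genomic positions.

    ``f`` is the one-way ANOVA ratio of between-group to within-group
    variance of per-sample methylation proportions.  ``finite`` flags
    sites whose within variance was positive; capped sites (f = 1/EPS_F)
    are excluded from ``mean_f``.
    """

    chrom: np.ndarray
    pos: np.ndarray
    f: np.ndarray
    finite: np.ndarray = None
    mean_f: float = None

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.f = np.asarray(self.f, dtype=float)
        if self.finite is None:
            self.finite = np.isfinite(self.f) & (self.f < 1.0 / EPS_F)
        else:
            self.finite = np.asarray(self.finite, dtype=bool)
        if self.mean_f is None:
            self.mean_f = float(self.f[self.finite].mean()) if self.finite.any() else 0.0

    def __len__(self) -> int:
        return len(self.f)


# ---------------------------------------------------------------------------
# coverage filter


def filter_by_coverage(table: MethylationTable, min_cov: int = 10) -> MethylationTable:
    """Retain sites with total coverage >= ``min_cov`` in *every* sample.

    Site order is preserved; an empty result only raises a warning.  The
    operation is idempotent.
    """
    mask = (table.t >= min_cov).all(axis=0)
    if not mask.any():
        warnings.warn("coverage filter removed every site", stacklevel=2)
    return table.subset_sites(mask)


# ---------------------------------------------------------------------------
# f-statistic


def site_fstat(beta_by_group: Sequence[np.ndarray]) -> float:
    """One-way ANOVA F of per-sample methylation proportions at one CpG.

    ``beta_by_group`` is a sequence of per-group proportion arrays.  A
    zero within-group variance with a positive between-group variance
    yields the capped value 1/EPS_F; zero between-group variance yields 0.
    """
    groups = [np.asarray(g, dtype=float) for g in beta_by_group]
    allv = np.concatenate(groups)
    if np.any((allv < 0) | (allv > 1)):
        raise ValueError("methylation proportions must lie in [0, 1]")
    if any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 samples per group")
    n = len(allv)
    k = len(groups)
    grand = allv.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    ms_between = ss_between / (k - 1)
    ms_within = ss_within / (n - k)
    if ms_within < EPS_F:
        return 0.0 if ms_between < EPS_F else 1.0 / EPS_F
    return float(ms_between / ms_within)


def fstat_track(table: MethylationTable, min_cov: int = 10) -> FStatTrack:
    """Vectorised f-statistic track over the coverage-filtered table."""
    ft = filter_by_coverage(table, min_cov) if min_cov else table
    idx1, idx2 = ft.group_indices()
    props = ft.levels()
    p1, p2 = props[idx1], props[idx2]
    n1, n2 = len(idx1), len(idx2)
    n = n1 + n2
    m1, m2 = p1.mean(axis=0), p2.mean(axis=0)
    grand = (n1 * m1 + n2 * m2) / n
    ss_b = n1 * (m1 - grand) ** 2 + n2 * (m2 - grand) ** 2
    ss_w = ((p1 - m1) ** 2).sum(axis=0) + ((p2 - m2) ** 2).sum(axis=0)
    ms_b = ss_b / 1.0
    ms_w = ss_w / (n - 2)
    f = np.empty(ft.n_sites)
    finite = ms_w >= EPS_F
    with np.errstate(divide="ignore", invalid="ignore"):
        f[finite] = ms_b[finite] / ms_w[finite]
    degenerate = ~finite
    f[degenerate & (ms_b >= EPS_F)] = 1.0 / EPS_F
    zero = degenerate & (ms_b < EPS_F)
    f[zero] = 0.0
    finite = finite | zero
    return FStatTrack(chrom=ft.chrom, pos=ft.pos, f=f, finite=finite)


# ---------------------------------------------------------------------------
# dispersion estimation and shrinkage


def estimate_dispersion(table: MethylationTable) -> np.ndarray:
    """Per-site method-of-moments beta-binomial dispersion estimates.

    Residual variation of sample proportions around their group means in
    excess of binomial sampling noise, on the phi scale of
    Var(m) = t*mu*(1-mu)*(1 + (t-1)*phi).  Sites where the estimator is
    undefined (no residual information) return NaN.
    """
    idx1, idx2 = table.group_indices()
    t = table.t.astype(float)
    obs = t > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(obs, table.m / np.maximum(t, 1.0), 0.0)
    num = np.zeros(table.n_sites)
    den = np.zeros(table.n_sites)
    for idx in (idx1, idx2):
        tg = t[idx]
        og = obs[idx]
        n_obs = og.sum(axis=0).astype(float)
        tot = np.where(og, tg, 0.0).sum(axis=0)
        mg = np.where(og, table.m[idx], 0.0).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            mu = np.where(tot > 0, mg / np.maximum(tot, 1.0), 0.0)
            # (n-1)/n corrects for estimating the group mean from the
            # same samples; with equal coverages the estimator is unbiased
            df_frac = np.where(n_obs > 0, (n_obs - 1.0) / np.maximum(n_obs, 1.0), 0.0)
        v = mu * (1.0 - mu)
        resid2 = np.where(og, (p[idx] - mu) ** 2, 0.0)
        binom_part = (np.where(og, v / np.maximum(tg, 1.0), 0.0)).sum(axis=0)
        num += resid2.sum(axis=0) - df_frac * binom_part
        den += df_frac * (v * np.where(og, (tg - 1.0) / np.maximum(tg, 1.0),
                                       0.0)).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = np.where(den > 0, num / np.maximum(den, 1e-300), np.nan)
    phi = np.where(np.isnan(phi), np.nan, np.clip(phi, 0.0, 1.0))
    return phi


def shrink_dispersion(
    phi_hat: np.ndarray,
    total_coverage: Optional[np.ndarray] = None,
    prior_coverage: float = 240.0,
    trim: float = 0.1,
) -> np.ndarray:
    """Shrink per-site dispersions toward their trimmed genome-wide mean.

    phi_shrunk = w * phi_hat + (1 - w) * phi_bar with w = T / (T + T0),
    where T is the site's total coverage over all samples and T0
    (``prior_coverage``) acts as the prior's pseudo-coverage, so the
    weight on the per-site estimate grows with the information at the
    site.  phi_bar is the ``trim``-trimmed mean of the finite estimates.
    Negative inputs are clamped to zero; NaN estimates shrink fully to
    phi_bar.
    """
    phi_hat = np.asarray(phi_hat, dtype=float)
    finite = np.isfinite(phi_hat)
    clamped = np.clip(np.where(finite, phi_hat, 0.0), 0.0, None)
    if finite.any():
        phi_bar = float(stats.trim_mean(clamped[finite], trim))
    else:
        phi_bar = 0.0
    if total_coverage is None:
        w = np.full(phi_hat.shape, 0.5)
    else:
        T = np.asarray(total_coverage, dtype=float)
        w = T / (T + prior_coverage)
    w = np.where(finite, w, 0.0)
    return w * clamped + (1.0 - w) * phi_bar


# ---------------------------------------------------------------------------
# beta-binomial Wald test


def betabin_wald_test(
    table: MethylationTable,
    phi: Optional[np.ndarray] = None,
    shrink: bool = True,
) -> pd.DataFrame:
    """Per-CpG two-group beta-binomial Wald test.

    For each group the methylation proportion is estimated as pooled
    reads sum(m)/sum(t) over samples with coverage; its variance uses the
    beta-binomial form sum_s t_s*mu*(1-mu)*(1+(t_s-1)*phi) / (sum_s t_s)^2.
    The Wald statistic (mu1-mu2)/se is referred to a standard normal,
    two-sided.  Sites with zero total coverage in a group are flagged
    untested (``tested`` False, NaN statistics).

    Returns a DataFrame with columns chrom, pos, mu1, mu2, stat, p, q,
    phi_shrunk, tested.
    """
    if phi is None:
        phi_hat = estimate_dispersion(table)
        if shrink:
            phi = shrink_dispersion(phi_hat, total_coverage=table.t.sum(axis=0))
        else:
            phi = np.where(np.isfinite(phi_hat), phi_hat, 0.0)
    else:
        phi = np.broadcast_to(np.asarray(phi, dtype=float), (table.n_sites,)).copy()

    idx1, idx2 = table.group_indices()
    mus, variances, covered = [], [], []
    for idx in (idx1, idx2):
        t = table.t[idx].astype(float)
        m = table.m[idx].astype(float)
        tot = t.sum(axis=0)
        ok = tot > 0
        with np.errstate(divide="ignore", invalid="ignore"):
            mu = np.where(ok, m.sum(axis=0) / np.maximum(tot, 1.0), np.nan)
        # continuity clamp keeps the variance positive at mu in {0, 1}
        mu_v = np.clip(mu, 1.0 / (tot + 2.0), 1.0 - 1.0 / (tot + 2.0))
        v_num = (t * (1.0 + (t - 1.0) * phi)).sum(axis=0) * mu_v * (1.0 - mu_v)
        with np.errstate(divide="ignore", invalid="ignore"):
            var = np.where(ok, v_num / np.maximum(tot, 1.0) ** 2, np.nan)
        mus.append(mu)
        variances.append(var)
        covered.append(ok)
    mu1, mu2 = mus
    tested = covered[0] & covered[1]
    se = np.sqrt(variances[0] + variances[1])
    diff = mu1 - mu2
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(se > 0, diff / np.maximum(se, 1e-300), 0.0)
    stat = np.where(np.abs(diff) < 1e-12, 0.0, stat)
    stat = np.where(tested, stat, np.nan)
    p = np.where(tested, 2.0 * stats.norm.sf(np.abs(stat)), np.nan)
    q = bh_fdr(p)
    return pd.DataFrame(
        {
            "chrom": table.chrom,
            "pos": table.pos,
            "mu1": mu1,
            "mu2": mu2,
            "stat": stat,
            "p": p,
            "q": q,
            "phi_shrunk": phi,
            "tested": tested,
        }
    )


def bh_fdr(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted values (NaNs propagated)."""
    p = np.asarray(p, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


# ---------------------------------------------------------------------------
# genome-wide summaries


def methylation_histogram(
    table: MethylationTable, bins: int = 10
) -> Tuple[np.ndarray, np.ndarray]:
    """Fractions of sites per pooled mean-methylation bin (sum to 1)."""
    levels = table.pooled_levels()
    levels = levels[np.isfinite(levels)]
    edges = np.linspace(0.0, 1.0, bins + 1)
    counts, _ = np.histogram(levels, bins=edges)
    fractions = counts / max(counts.sum(), 1)
    return edges, fractions


def bimodality_fractions(
    table: MethylationTable, high: float = 0.8, low: float = 0.1
) -> Tuple[float, float]:
    """(fraction of sites with mean level > high, fraction < low)."""
    levels = table.pooled_levels()
    levels = levels[np.isfinite(levels)]
    n = max(len(levels), 1)
    return float((levels > high).sum() / n), float((levels < low).sum() / n)


# ---------------------------------------------------------------------------
# model / results facade


class DifferentialMethylation:
    """Two-group differential methylation model over a count table.

    Wraps coverage filtering, the beta-binomial locus test and the
    f-statistic track behind a fit() interface::

        model = DifferentialMethylation(table)
        res = model.fit(min_cov=10)
        res.summary()
        dmrs = res.call_dmrs(penalty=0.02)
    """

    def __init__(self, table: MethylationTable):
        self.table = table

    @classmethod
    def from_dataframe(
        cls, counts: pd.DataFrame, groups: Dict[str, str]
    ) -> "DifferentialMethylation":
        """Build from a long-format frame with chrom/pos plus m_<s>/t_<s> columns."""
        samples = [c[2:] for c in counts.columns if c.startswith("m_")]
        m = np.vstack([counts[f"m_{s}"].to_numpy() for s in samples])
        t = np.vstack([counts[f"t_{s}"].to_numpy() for s in samples])
        table = MethylationTable(
            chrom=counts["chrom"].to_numpy(),
            pos=counts["pos"].to_numpy(),
            m=m,
            t=t,
            samples=samples,
            groups=groups,
        )
        return cls(table)

    def fit(
        self,
        min_cov: int = 10,
        phi: Optional[np.ndarray] = None,
        shrink: bool = True,
    ) -> "DifferentialMethylationResults":
        # the locus test uses every sample with reads at a site; the strict
        # all-sample coverage filter applies only to the f/PCA track
        sites = betabin_wald_test(self.table, phi=phi, shrink=shrink)
        filtered = filter_by_coverage(self.table, min_cov)
        track = fstat_track(filtered, min_cov=0)
        return DifferentialMethylationResults(self, filtered, sites, track, min_cov)


@dataclass
class DifferentialMethylationResults:
    """Per-site test results plus the f-statistic track of a fit."""

    model: DifferentialMethylation
    filtered_table: MethylationTable
    sites: pd.DataFrame
    track: FStatTrack
    min_cov: int

    def significant(self, alpha: float = 0.05, kind: str = "q") -> pd.DataFrame:
        return self.sites[self.sites[kind] < alpha]

    def call_dmrs(self, penalty: float = 0.02):
        from .dmr import compute_score_track, call_dmrs

        return call_dmrs(compute_score_track(self.track, penalty=penalty))

    def summary(self) -> str:
        g1, g2 = self.filtered_table.group_names
        n_sig = int((self.sites["q"] < 0.05).sum())
        lines = [
            "Differential methylation (beta-binomial Wald test)",
            "=" * 50,
            f"groups:              {g1} vs {g2}",
            f"samples:             {self.filtered_table.n_samples}",
            f"sites tested:        {int(self.sites['tested'].sum())}",
            f"f-track sites:       {len(self.track)}"
            f" (coverage >= {self.min_cov} in all samples)",
            f"significant q<0.05:  {n_sig}",
            f"mean dispersion:     {np.nanmean(self.sites['phi_shrunk']):.4f}",
            f"mean f-statistic:    {self.track.mean_f:.3f}",
        ]
        return "\n".join(lines)
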