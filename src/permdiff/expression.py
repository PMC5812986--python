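"""Differential expression, volcano classification, k-means profiles,
directional hypergeometric gene-set tests and expression-matched
background sampling.

The per-gene test is a deliberately plain Welch two-sample t-test on
log2(abundance + 1); the scientific weight rests on the permutation
layer wrapped around it, which is method-agnostic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .methylation import bh_fdr


@dataclass
class ExpressionTable:
    """Gene × sample FPKM-like abundances with a two-group design."""

    abundance: pd.DataFrame  # genes x samples, nonnegative
    groups: Dict[str, str]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if (self.abundance.to_numpy() < 0).any():
            raise ValueError("abundances must be nonnegative")
        labels = pd.Series([self.groups[s] for s in self.abundance.columns])
        counts = labels.value_counts()
        if len(counts) != 2 or counts.min() < 2:
            raise ValueError("need >= 2 samples in each of two groups")

    @property
    def samples(self) -> List[str]:
        return list(self.abundance.columns)

    @property
    def genes(self) -> pd.Index:
        return self.abundance.index

    @property
    def group_names(self) -> Tuple[str, str]:
        seen: List[str] = []
        for s in self.samples:
            g = self.groups[s]
            if g not in seen:
                seen.append(g)
        return seen[0], seen[1]

    def group_columns(self) -> Tuple[List[str], List[str]]:
        g1, g2 = self.group_names
        return (
            [s for s in self.samples if self.groups[s] == g1],
            [s for s in self.samples if self.groups[s] == g2],
        )

    def relabel(self, groups: Dict[str, str]) -> "ExpressionTable":
        return ExpressionTable(self.abundance, dict(groups))


def de_test(table: ExpressionTable, groups: Optional[Dict[str, str]] = None) -> pd.DataFrame:
    """Welch t-test per gene on log2(abundance + 1), with BH FDR.

    log2fc is log2 of the (mean + 1) abundance ratio, treatment over
    control, where 'treatment' is the second group label.  Genes with
    zero variance in both groups get p = 1.
    """
    if groups is not None:
        table = table.relabel(groups)
    cols1, cols2 = table.group_columns()
    x = np.log2(table.abundance[cols1].to_numpy(dtype=float) + 1.0)
    y = np.log2(table.abundance[cols2].to_numpy(dtype=float) + 1.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(y, x, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
        t = np.asarray(res.statistic, dtype=float)
    degenerate = ~np.isfinite(p)
    p[degenerate] = 1.0
    t[degenerate] = 0.0
    mean1 = table.abundance[cols1].to_numpy(dtype=float).mean(axis=1)
    mean2 = table.abundance[cols2].to_numpy(dtype=float).mean(axis=1)
    log2fc = np.log2(mean2 + 1.0) - np.log2(mean1 + 1.0)
    return pd.DataFrame(
        {"log2fc": log2fc, "stat": t, "p": p, "q": bh_fdr(p)},
        index=table.genes,
    )


def classify_volcano(
    de: pd.DataFrame, fc_threshold: float = 2.0, q_threshold: float = 0.05
) -> pd.Series:
    """Four-way volcano classes: none / fc_only / q_only / both.

    Fold-change calls require |fold change| strictly greater than
    ``fc_threshold`` (i.e. |log2fc| > log2(fc_threshold)); q calls
    require q strictly below ``q_threshold``.
    """
    big_fc = np.abs(de["log2fc"].to_numpy()) > np.log2(fc_threshold)
    small_q = de["q"].to_numpy() < q_threshold
    labels = np.where(
        big_fc & small_q, "both",
        np.where(big_fc, "fc_only", np.where(small_q, "q_only", "none")),
    )
    return pd.Series(labels, index=de.index, name="volcano_class")


def kmeans_expression_clusters(
    matrix: pd.DataFrame, k: int = 12, seed: int = 0
) -> Tuple[pd.Series, pd.DataFrame]:
    """k-means on log2(abundance + 1) gene profiles.

    Returns (gene→cluster labels, cluster-mean profiles min–max scaled
    per row, as they would be displayed in a heat map).
    """
    if k > len(matrix):
        raise ValueError("k exceeds the number of genes")
    logm = np.log2(matrix.to_numpy(dtype=float) + 1.0)
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    labels = km.fit_predict(logm)
    means = pd.DataFrame(
        km.cluster_centers_, columns=matrix.columns,
        index=pd.RangeIndex(k, name="cluster"),
    )
    lo = means.min(axis=1)
    span = (means.max(axis=1) - lo).replace(0.0, 1.0)
    scaled = means.sub(lo, axis=0).div(span, axis=0)
    return pd.Series(labels, index=matrix.index, name="cluster"), scaled


@dataclass
class GeneSetTestResult:
    """Counts and upper-tail hypergeometric p for a directional set test."""

    set_size: int            # K: genes in the set present in the universe
    tested_in_set: int       # genes in the set with a usable test result
    significant_in_set: int  # k: set genes significant in the stated direction
    background_size: int     # N: universe size
    background_significant: int  # M: universe genes significant in direction
    p_hyper: float


def directional_enrichment(K: int, k: int, N: int, M: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, M, K).

    The probability of drawing at least ``k`` direction-significant
    genes in a set of ``K`` from a universe of ``N`` genes of which
    ``M`` are direction-significant.
    """
    if not (0 <= k <= K <= N) or not (0 <= M <= N):
        raise ValueError("inconsistent hypergeometric counts")
    if k > M:
        raise ValueError("k cannot exceed M")
    return float(stats.hypergeom.sf(k - 1, N, M, K))


def gene_set_test(
    gene_set: Iterable[str],
    de: pd.DataFrame,
    direction: str = "down",
    p_threshold: float = 0.05,
    threshold_kind: str = "p",
    universe: Optional[Iterable[str]] = None,
) -> GeneSetTestResult:
    """Directional hypergeometric enrichment of a gene set.

    Counts genes significant at ``threshold_kind`` < ``p_threshold``
    with the stated fold-change direction, in the set versus the
    universe (default: all genes in ``de``).
    """
    if direction not in ("down", "up"):
        raise ValueError("direction must be 'down' or 'up'")
    universe_idx = de.index if universe is None else de.index.intersection(list(universe))
    sub = de.loc[universe_idx]
    sig = (sub[threshold_kind].to_numpy() < p_threshold)
    if direction == "down":
        sig &= sub["log2fc"].to_numpy() < 0
    else:
        sig &= sub["log2fc"].to_numpy() > 0
    in_set = sub.index.isin(list(gene_set))
    K = int(in_set.sum())
    k = int((sig & in_set).sum())
    N = len(sub)
    M = int(sig.sum())
    return GeneSetTestResult(
        set_size=K,
        tested_in_set=int((in_set & np.isfinite(sub["p"].to_numpy())).sum()),
        significant_in_set=k,
        background_size=N,
        background_significant=M,
        p_hyper=directional_enrichment(K, k, N, M),
    )


def expression_matched_background(
    targets: Sequence[str],
    universe_abundance: pd.Series,
    n_bins: int = 10,
    seed: int = 0,
) -> List[str]:
    """Sample non-target genes matching the targets' expression profile.

    The universe is cut into ``n_bins`` expression quantile bins; from
    each bin as many non-targets are drawn (without replacement when
    possible) as there are targets in it.  Bins with too few non-targets
    fall back to sampling with replacement, with a warning.
    """
    targets = list(targets)
    missing = set(targets) - set(universe_abundance.index)
    if missing:
        raise ValueError(f"targets absent from universe: {sorted(missing)[:5]}")
    bins = pd.qcut(universe_abundance.rank(method="first"), n_bins, labels=False)
    rng = np.random.default_rng(seed)
    target_set = set(targets)
    background: List[str] = []
    for b in range(n_bins):
        genes_in_bin = universe_abundance.index[bins == b]
        need = sum(1 for g in genes_in_bin if g in target_set)
        pool = [g for g in genes_in_bin if g not in target_set]
        if need == 0:
            continue
        if len(pool) >= need:
            background.extend(rng.choice(pool, size=need, replace=False))
        else:
            warnings.warn(
                f"expression bin {b}: only {len(pool)} non-targets for "
                f"{need} targets; sampling with replacement",
                stacklevel=2,
            )
            if not pool:  # bin exhausted entirely: fall back to all non-targets
                pool = [g for g in universe_abundance.index if g not in target_set]
            background.extend(rng.choice(pool, size=need, replace=True))
    return background


# ---------------------------------------------------------------------------
# model / results facade


class DifferentialExpression:
    """Two-group differential expression model.

    ::

        res = DifferentialExpression(table).fit()
        print(res.summary())
        labels, profiles = res.cluster(k=12, seed=0)
    """

    def __init__(self, table: ExpressionTable):
        self.table = table

    @classmethod
    def from_dataframe(
        cls, abundance: pd.DataFrame, groups: Dict[str, str]
    ) -> "DifferentialExpression":
        return cls(ExpressionTable(abundance, groups))

    def fit(
        self, fc_threshold: float = 2.0, q_threshold: float = 0.05
    ) -> "DifferentialExpressionResults":
        de = de_test(self.table)
        de["volcano_class"] = classify_volcano(de, fc_threshold, q_threshold)
        return DifferentialExpressionResults(self, de, fc_threshold, q_threshold)


@dataclass
class DifferentialExpressionResults:
    model: DifferentialExpression
    genes: pd.DataFrame
    fc_threshold: float
    q_threshold: float

    def significant(self, alpha: float = None) -> pd.DataFrame:
        alpha = self.q_threshold if alpha is None else alpha
        return self.genes[self.genes["q"] < alpha]

    def cluster(self, k: int = 12, seed: int = 0, subset: Optional[pd.Index] = None):
        idx = self.significant().index if subset is None else subset
        return kmeans_expression_clusters(
            self.model.table.abundance.loc[idx], k=k, seed=seed
        )

    def gene_set_test(self, gene_set, **kwargs) -> GeneSetTestResult:
        return gene_set_test(gene_set, self.genes, **kwargs)

    def summary(self) -> str:
        g1, g2 = self.model.table.group_names
        vc = self.genes["volcano_class"].value_counts()
        sig = self.significant()
        n_down = int((sig["log2fc"] < 0).sum())
        lines = [
            "Differential expression (Welch t on log2(FPKM + 1))",
            "=" * 50,
            f"groups:                 {g1} vs {g2}",
            f"genes tested:           {len(self.genes)}",
            f"significant q<{self.q_threshold:g}:     {len(sig)}"
            f" ({n_down} down in {g2})",
            f"|FC|>{self.fc_threshold:g} only:            {int(vc.get('fc_only', 0))}",
            f"q only:                 {int(vc.get('q_only', 0))}",
            f"both:                   {int(vc.get('both', 0))}",
        ]
        return "\n".join(lines)
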