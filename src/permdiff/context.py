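"""Genomic-feature derivation, site annotation and TSS-centred analyses.

Derives promoter / exon / intron / island / shore / intergenic interval
sets from an annotation, tests DML enrichment per feature (Fisher exact)
and per TSS-distance window (hypergeometric, Holm-adjusted), builds
nested TSS-window methylation matrices and runs centred unscaled PCA
with group-segregation tests, assigns regions to nearest genes and
correlates promoter methylation with expression.

All intervals are 0-based half-open.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .methylation import MethylationTable

Intervals = Dict[str, np.ndarray]  # chrom -> (n, 2) sorted, merged


# ---------------------------------------------------------------------------
# interval arithmetic


def merge_intervals(iv: np.ndarray) -> np.ndarray:
    """Sort and merge overlapping/adjacent half-open intervals."""
    iv = np.asarray(iv, dtype=np.int64).reshape(-1, 2)
    if len(iv) == 0:
        return iv
    iv = iv[np.argsort(iv[:, 0], kind="stable")]
    out = [list(iv[0])]
    for s, e in iv[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.asarray(out, dtype=np.int64)


def subtract_intervals(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Set difference a \\ b for merged interval arrays."""
    a = merge_intervals(a)
    b = merge_intervals(b)
    out = []
    for s, e in a:
        cur = s
        for bs, be in b:
            if be <= cur or bs >= e:
                continue
            if bs > cur:
                out.append([cur, bs])
            cur = max(cur, be)
            if cur >= e:
                break
        if cur < e:
            out.append([cur, e])
    return np.asarray(out, dtype=np.int64).reshape(-1, 2)


def complement_intervals(a: np.ndarray, length: int) -> np.ndarray:
    return subtract_intervals(np.array([[0, length]]), a)


def pad_intervals(a: np.ndarray, pad: int, length: int) -> np.ndarray:
    a = np.asarray(a, dtype=np.int64).reshape(-1, 2)
    if len(a) == 0:
        return a
    padded = np.column_stack(
        [np.clip(a[:, 0] - pad, 0, length), np.clip(a[:, 1] + pad, 0, length)]
    )
    return merge_intervals(padded)


def positions_in_intervals(pos: np.ndarray, iv: np.ndarray) -> np.ndarray:
    """Boolean membership of positions in merged half-open intervals."""
    pos = np.asarray(pos, dtype=np.int64)
    if len(iv) == 0:
        return np.zeros(len(pos), dtype=bool)
    idx = np.searchsorted(iv[:, 0], pos, side="right") - 1
    ok = idx >= 0
    res = np.zeros(len(pos), dtype=bool)
    res[ok] = pos[ok] < iv[idx[ok], 1]
    return res


@dataclass
class FeatureSet:
    """Labelled genomic interval collections (merged, per chromosome)."""

    features: Dict[str, Intervals]

    def labels(self) -> List[str]:
        return list(self.features)

    def membership(self, chrom: np.ndarray, pos: np.ndarray, label: str) -> np.ndarray:
        chrom = np.asarray(chrom)
        pos = np.asarray(pos, dtype=np.int64)
        iv_by_chrom = self.features[label]
        out = np.zeros(len(pos), dtype=bool)
        for c in pd.unique(chrom):
            sel = chrom == c
            out[sel] = positions_in_intervals(pos[sel], iv_by_chrom.get(c, np.empty((0, 2), np.int64)))
        return out


def derive_feature_sets(
    model,
    promoter_bp: int = 5000,
    shore_bp: int = 5000,
    intergenic_bp: int = 50000,
) -> FeatureSet:
    """Derive the standard feature categories from an annotation.

    promoters: ``promoter_bp`` strand-aware upstream of each TSS
    (clamped at chromosome bounds); introns: transcript minus exon;
    shores: ``shore_bp`` flanks of CpG islands excluding island bp;
    intergenic: the complement of gene bodies padded by
    ``intergenic_bp``.  Categories may overlap each other.
    """
    chroms = list(model.chrom_sizes)
    empty = lambda: {c: np.empty((0, 2), np.int64) for c in chroms}
    tx, ex, prom, isl = ({c: [] for c in chroms} for _ in range(4))
    for t in model.transcripts:
        tx[t.chrom].append([t.start, t.end])
        for es, ee in t.exons:
            ex[t.chrom].append([es, ee])
        L = model.chrom_sizes[t.chrom]
        if t.strand == "+":
            prom[t.chrom].append([max(0, t.tss - promoter_bp), min(t.tss, L)])
        else:
            prom[t.chrom].append([max(0, t.tss), min(t.tss + promoter_bp, L)])
    for c, s, e in model.cpg_islands:
        isl[c].append([s, e])

    features: Dict[str, Intervals] = {
        "transcript": {}, "exon": {}, "intron": {}, "promoter": {},
        "cpg_island": {}, "island_shore": {}, "intergenic": {},
    }
    for c in chroms:
        L = model.chrom_sizes[c]
        tx_m = merge_intervals(np.asarray(tx[c]).reshape(-1, 2))
        ex_m = merge_intervals(np.asarray(ex[c]).reshape(-1, 2))
        isl_m = merge_intervals(np.asarray(isl[c]).reshape(-1, 2))
        features["transcript"][c] = tx_m
        features["exon"][c] = ex_m
        features["intron"][c] = subtract_intervals(tx_m, ex_m)
        features["promoter"][c] = merge_intervals(np.asarray(prom[c]).reshape(-1, 2))
        features["cpg_island"][c] = isl_m
        features["island_shore"][c] = subtract_intervals(
            pad_intervals(isl_m, shore_bp, L), isl_m
        )
        features["intergenic"][c] = complement_intervals(
            pad_intervals(tx_m, intergenic_bp, L), L
        )
    return FeatureSet(features)


# ---------------------------------------------------------------------------
# enrichment


def feature_enrichment(
    dml_chrom: np.ndarray,
    dml_pos: np.ndarray,
    all_chrom: np.ndarray,
    all_pos: np.ndarray,
    features: FeatureSet,
) -> pd.DataFrame:
    """Per-feature DML enrichment: log2 ratio and two-sided Fisher p.

    For each feature, the 2×2 table opposes DML / non-DML membership in
    / out of the feature among all measured sites.  The log2 ratio is
    log2((k / n_dml) / (K / n_sites)).  Features holding no measured
    site are skipped with a flag.
    """
    n_dml = len(dml_pos)
    n_sites = len(all_pos)
    rows = []
    for label in features.labels():
        K = int(features.membership(all_chrom, all_pos, label).sum())
        k = int(features.membership(dml_chrom, dml_pos, label).sum())
        if K == 0:
            rows.append({"feature": label, "n_dml": k, "n_sites": 0,
                         "log2_ratio": np.nan, "p": np.nan, "skipped": True})
            continue
        table = [[k, n_dml - k], [K - k, (n_sites - n_dml) - (K - k)]]
        _, p = stats.fisher_exact(table, alternative="two-sided")
        with np.errstate(divide="ignore"):
            ratio = np.log2((k / n_dml) / (K / n_sites)) if n_dml else np.nan
        rows.append({"feature": label, "n_dml": k, "n_sites": K,
                     "log2_ratio": ratio, "p": p, "skipped": False})
    return pd.DataFrame(rows).set_index("feature")


def signed_tss_distance(
    chrom: np.ndarray, pos: np.ndarray, model
) -> np.ndarray:
    """Strand-oriented signed distance of each site to its nearest TSS.

    Negative values lie upstream of the nearest TSS, positive values
    downstream, 0 at the TSS itself.  Nearness is by absolute distance;
    ties resolve to the smaller TSS coordinate.
    """
    chrom = np.asarray(chrom)
    pos = np.asarray(pos, dtype=np.int64)
    out = np.full(len(pos), np.iinfo(np.int64).max, dtype=np.int64)
    tss_by_chrom: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
    for t in model.transcripts:
        tss_by_chrom.setdefault(t.chrom, ([], []))
        tss_by_chrom[t.chrom][0].append(t.tss)
        tss_by_chrom[t.chrom][1].append(1 if t.strand == "+" else -1)
    for c, (tpos, tsign) in tss_by_chrom.items():
        order = np.argsort(tpos, kind="stable")
        tpos = np.asarray(tpos, dtype=np.int64)[order]
        tsign = np.asarray(tsign, dtype=np.int64)[order]
        sel = np.where(chrom == c)[0]
        if len(sel) == 0:
            continue
        p = pos[sel]
        right = np.searchsorted(tpos, p, side="left")
        left = np.clip(right - 1, 0, len(tpos) - 1)
        right = np.clip(right, 0, len(tpos) - 1)
        d_left = np.abs(p - tpos[left])
        d_right = np.abs(p - tpos[right])
        use_left = d_left <= d_right
        nearest = np.where(use_left, left, right)
        out[sel] = (p - tpos[nearest]) * tsign[nearest]
    return out


def tss_window_enrichment(
    signed_dist: np.ndarray,
    is_dml: np.ndarray,
    window_bp: int = 1000,
    step_bp: int = 500,
    max_dist: int = 5000,
) -> pd.DataFrame:
    """DML enrichment in overlapping distance windows around TSSs.

    Windows of width ``window_bp`` advance by ``step_bp`` across
    [-max_dist, max_dist).  Each non-empty window gets an upper-tail
    hypergeometric p for its DML count given the window's site total,
    the overall site total within the span and the overall DML count;
    p-values are Holm-adjusted across the non-empty windows.
    """
    signed_dist = np.asarray(signed_dist, dtype=np.int64)
    is_dml = np.asarray(is_dml, dtype=bool)
    in_span = (signed_dist >= -max_dist) & (signed_dist < max_dist)
    N = int(in_span.sum())
    M = int((is_dml & in_span).sum())
    rows = []
    start = -max_dist
    while start + window_bp <= max_dist:
        lo, hi = start, start + window_bp
        sel = (signed_dist >= lo) & (signed_dist < hi)
        n = int(sel.sum())
        if n > 0:
            k = int((is_dml & sel).sum())
            p = float(stats.hypergeom.sf(k - 1, N, M, n))
            rows.append({"window_start": lo, "window_end": hi,
                         "n_sites": n, "n_dml": k, "p": p})
        start += step_bp
    df = pd.DataFrame(rows, columns=["window_start", "window_end",
                                     "n_sites", "n_dml", "p"])
    if len(df):
        df["p_holm"] = multipletests(df["p"].to_numpy(), method="holm")[1]
    else:
        df["p_holm"] = pd.Series(dtype=float)
    return df


def distance_stat_profile(
    signed_dist: np.ndarray,
    abs_stat: np.ndarray,
    bandwidth: float = 50.0,
    max_dist: int = 5000,
) -> pd.DataFrame:
    """Mean |statistic| per signed TSS distance plus a smoothed curve.

    The unsmoothed profile is the per-distance mean of ``abs_stat``; the
    smoothed curve is a Gaussian-kernel weighted mean over the
    per-distance means, weighted additionally by the number of sites at
    each distance.
    """
    signed_dist = np.asarray(signed_dist, dtype=np.int64)
    abs_stat = np.asarray(abs_stat, dtype=float)
    if not np.all(np.isfinite(abs_stat)):
        raise ValueError("statistics must be finite")
    sel = np.abs(signed_dist) <= max_dist
    df = pd.DataFrame({"dist": signed_dist[sel], "stat": abs_stat[sel]})
    grouped = df.groupby("dist")["stat"].agg(["mean", "count"]).reset_index()
    d = grouped["dist"].to_numpy(dtype=float)
    means = grouped["mean"].to_numpy()
    counts = grouped["count"].to_numpy(dtype=float)
    smooth = np.empty_like(means)
    for i, x in enumerate(d):
        w = counts * np.exp(-0.5 * ((d - x) / bandwidth) ** 2)
        smooth[i] = np.sum(w * means) / np.sum(w)
    return pd.DataFrame({"dist": d.astype(np.int64), "mean_stat": means,
                         "n_sites": counts.astype(int), "smoothed": smooth})


# ---------------------------------------------------------------------------
# nested TSS windows and PCA segregation

DEFAULT_EXTENTS = (600, 1200, 1800, 2400, 3000, 3600, 4200, 4800)


def _window_site_indices(
    table: MethylationTable, model, side: str, extent: int
) -> Tuple[np.ndarray, np.ndarray]:
    """(site_index, tss_index) occurrence pairs for one nested window.

    A site occurs once per TSS whose strand-oriented window of signed
    extent covers it: upstream windows cover oriented distances
    [-extent, 0), downstream windows [0, extent).
    """
    site_idx: List[int] = []
    tss_idx: List[int] = []
    chrom = np.asarray(table.chrom)
    pos = np.asarray(table.pos, dtype=np.int64)
    for j, t in enumerate(model.transcripts):
        sel = np.where(chrom == t.chrom)[0]
        if len(sel) == 0:
            continue
        p = pos[sel]
        sign = 1 if t.strand == "+" else -1
        oriented = (p - t.tss) * sign
        if side == "upstream":
            hit = (oriented >= -extent) & (oriented < 0)
        else:
            hit = (oriented >= 0) & (oriented < extent)
        site_idx.extend(sel[hit])
        tss_idx.extend([j] * int(hit.sum()))
    return np.asarray(site_idx, dtype=np.int64), np.asarray(tss_idx, dtype=np.int64)


def nested_window_methylation(
    table: MethylationTable,
    model,
    extents: Sequence[int] = DEFAULT_EXTENTS,
    weighted: bool = False,
) -> pd.DataFrame:
    """Sample × nested-window mean methylation matrix.

    Columns are signed extents (negative = upstream), e.g. -2400 covers
    all CpG occurrences within 2400 bp upstream of any TSS.  Entries are
    means of per-site methylation levels over occurrences (per-site
    levels are read-count weighted within a site only when
    ``weighted``); windows with no covered CpG are NaN.
    """
    levels = table.levels()
    t = table.t.astype(float)
    cols = {}
    for side, sgn in (("upstream", -1), ("downstream", 1)):
        for extent in extents:
            si, _ = _window_site_indices(table, model, side, extent)
            name = sgn * extent
            if len(si) == 0:
                cols[name] = np.full(table.n_samples, np.nan)
                continue
            lv = levels[:, si]
            if weighted:
                w = t[:, si]
                with np.errstate(invalid="ignore", divide="ignore"):
                    vals = np.nansum(np.where(np.isfinite(lv), lv * w, 0), axis=1) / \
                        np.where(np.isfinite(lv), w, 0).sum(axis=1)
            else:
                vals = np.nanmean(lv, axis=1)
            cols[name] = vals
    order = sorted(cols, key=lambda x: (x >= 0, abs(x) if x < 0 else x))
    mat = pd.DataFrame({k: cols[k] for k in order}, index=table.samples)
    mat.columns.name = "window"
    return mat


def tss_window_sample_matrix(
    table: MethylationTable, model, side: str, extent: int
) -> pd.DataFrame:
    """Sample × TSS matrix of window mean methylation for one window.

    TSSs with no covered CpG in the window are dropped (missing columns
    removed).  This is the per-window input of the nested-window PCA.
    """
    si, ti = _window_site_indices(table, model, side, extent)
    n_t = len(model.transcripts)
    levels = table.levels()
    mat = np.full((table.n_samples, n_t), np.nan)
    if len(si):
        for j in np.unique(ti):
            cols = si[ti == j]
            mat[:, j] = np.nanmean(levels[:, cols], axis=1)
    df = pd.DataFrame(mat, index=table.samples,
                      columns=[t.transcript_id for t in model.transcripts])
    return df.dropna(axis=1, how="any")


@dataclass
class SegregationResult:
    """PC1 scores and group-separation tests for one window PCA."""

    pc1_scores: pd.Series
    explained_variance_ratio: float
    t_p: float
    mwu_p: float
    separated: bool


def pca_group_segregation(
    matrix: pd.DataFrame, groups: Dict[str, str]
) -> SegregationResult:
    """Centred, unscaled PCA; PC1 scores tested for group separation.

    Columns containing missing values are dropped.  PC1 scores are
    compared between groups by a two-sample t-test and an exact
    Mann–Whitney U test; ``separated`` flags disjoint group ranges on
    PC1 (complete separation in the first dimension).
    """
    X = matrix.dropna(axis=1, how="any")
    data = X.to_numpy(dtype=float)
    if data.shape[1] == 0:
        raise ValueError("no complete columns to analyse")
    centred = data - data.mean(axis=0)
    if np.allclose(centred, 0):
        raise ValueError("constant matrix: PCA undefined")
    u, sv, vt = np.linalg.svd(centred, full_matrices=False)
    scores = pd.Series(u[:, 0] * sv[0], index=X.index, name="PC1")
    evr = float(sv[0] ** 2 / np.sum(sv ** 2))
    labels = np.array([groups[s] for s in X.index])
    names = pd.unique(labels)
    if len(names) != 2:
        raise ValueError("need exactly two groups")
    a = scores[labels == names[0]].to_numpy()
    b = scores[labels == names[1]].to_numpy()
    if min(len(a), len(b)) < 2:
        raise ValueError("need >= 2 samples per group")
    t_p = float(stats.ttest_ind(a, b, equal_var=True).pvalue)
    mwu_p = float(stats.mannwhitneyu(a, b, alternative="two-sided",
                                     method="exact").pvalue)
    separated = bool(a.max() < b.min() or b.max() < a.min())
    return SegregationResult(scores, evr, t_p, mwu_p, separated)


def nested_window_segregation(
    table: MethylationTable,
    model,
    extents: Sequence[int] = DEFAULT_EXTENTS,
) -> pd.DataFrame:
    """Per nested TSS window: PCA of the sample × TSS matrix + tests."""
    rows = []
    for side, sgn in (("upstream", -1), ("downstream", 1)):
        for extent in extents:
            mat = tss_window_sample_matrix(table, model, side, extent)
            if mat.shape[1] == 0:
                rows.append({"window": sgn * extent, "n_tss": 0,
                             "t_p": np.nan, "mwu_p": np.nan,
                             "separated": False, "skipped": True})
                continue
            res = pca_group_segregation(mat, table.groups)
            rows.append({"window": sgn * extent, "n_tss": mat.shape[1],
                         "t_p": res.t_p, "mwu_p": res.mwu_p,
                         "separated": res.separated, "skipped": False})
    return pd.DataFrame(rows).set_index("window")


# ---------------------------------------------------------------------------
# nearest genes and methylation–expression association


def nearest_gene_assignment(
    regions: pd.DataFrame,
    genes: pd.DataFrame,
    max_dist: int = 40000,
) -> pd.DataFrame:
    """Nearest gene per region by interval distance (0 when overlapping).

    ``regions`` and ``genes`` need chrom/start/end columns; genes also a
    ``gene_id``.  Regions farther than ``max_dist`` from every gene get
    gene_id None.  Ties break to the smaller gene start.
    """
    rows = []
    genes_by_chrom = {c: g.sort_values(["start", "end"]).reset_index(drop=True)
                      for c, g in genes.groupby("chrom")}
    for _, r in regions.iterrows():
        g = genes_by_chrom.get(r["chrom"])
        best = (None, None)
        if g is not None:
            gs = g["start"].to_numpy()
            ge = g["end"].to_numpy()
            # half-open gap: distance between [a,b) and [c,d) is max(c-b, a-d, 0)
            dist = np.maximum(np.maximum(gs - r["end"], r["start"] - ge), 0)
            order = np.lexsort((gs, dist))
            i = order[0]
            if dist[i] <= max_dist:
                best = (g.loc[i, "gene_id"], int(dist[i]))
        rows.append({"chrom": r["chrom"], "start": r["start"], "end": r["end"],
                     "gene_id": best[0], "distance": best[1]})
    return pd.DataFrame(rows)


def promoter_methylation(
    table: MethylationTable, model, promoter_bp: int = 5000
) -> pd.DataFrame:
    """Gene × sample mean promoter methylation (genes without covered
    promoter CpGs dropped)."""
    chrom = np.asarray(table.chrom)
    pos = np.asarray(table.pos, dtype=np.int64)
    levels = table.levels()
    rows = {}
    for t in model.transcripts:
        sel = np.where(chrom == t.chrom)[0]
        if len(sel) == 0:
            continue
        p = pos[sel]
        if t.strand == "+":
            hit = (p >= t.tss - promoter_bp) & (p < t.tss)
        else:
            hit = (p >= t.tss) & (p < t.tss + promoter_bp)
        if hit.any():
            rows[t.transcript_id] = np.nanmean(levels[:, sel[hit]], axis=1)
    df = pd.DataFrame(rows, index=table.samples).T
    df.index.name = "gene_id"
    return df


@dataclass
class AssociationResult:
    rho: float
    p_perm: float
    n_genes: int
    degenerate: bool


def promoter_meth_expr_association(
    promoter_meth: pd.DataFrame,
    expression: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
) -> AssociationResult:
    """Spearman correlation of mean promoter methylation vs mean
    log-expression across matched genes, with a permutation p-value.

    Both inputs are gene × sample frames; genes are matched on index.
    Fewer than 3 matched genes is an error; a constant methylation (or
    expression) vector is flagged degenerate with rho = 0 by convention.
    """
    common = promoter_meth.index.intersection(expression.index)
    if len(common) < 3:
        raise ValueError("need >= 3 matched genes")
    x = promoter_meth.loc[common].mean(axis=1).to_numpy()
    y = np.log2(expression.loc[common].mean(axis=1).to_numpy() + 1.0)
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        return AssociationResult(0.0, 1.0, len(common), True)
    rho = float(stats.spearmanr(x, y).statistic)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        r = stats.spearmanr(x, rng.permutation(y)).statistic
        if abs(r) >= abs(rho):
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    return AssociationResult(rho, float(p), len(common), False)
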