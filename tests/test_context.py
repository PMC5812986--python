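"""Feature derivation, enrichment, TSS-window analyses, PCA
segregation, nearest genes and methylation–expression association."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from permdiff import (
    SimulationConfig,
    derive_feature_sets,
    distance_stat_profile,
    feature_enrichment,
    filter_by_coverage,
    nearest_gene_assignment,
    nested_window_methylation,
    nested_window_segregation,
    pca_group_segregation,
    promoter_meth_expr_association,
    promoter_methylation,
    signed_tss_distance,
    simulate_annotation,
    simulate_methylome,
    tss_window_enrichment,
    tss_window_sample_matrix,
)
from permdiff.context import (
    merge_intervals,
    positions_in_intervals,
    subtract_intervals,
)
from permdiff.simulate import GenomeModel, Transcript

from conftest import make_table, null_config


def tiny_model():
    """Two transcripts (one per strand), one island, hand-laid CpGs."""
    tx = [
        Transcript("gA", "chr1", 10_000, 12_000, "+", 10_000,
                   ((10_000, 10_500), (11_000, 12_000))),
        Transcript("gB", "chr1", 30_000, 32_000, "-", 32_000,
                   ((30_000, 32_000),)),
    ]
    islands = [("chr1", 9_800, 10_300)]
    cpg = np.array([5_000, 9_900, 10_100, 10_900, 31_000, 33_000, 150_000])
    return GenomeModel({"chr1": 200_000}, tx, islands,
                       np.array(["chr1"] * len(cpg)), cpg)


# ---------------------------------------------------------------------------
# feature derivation


def test_minus_strand_promoter_reflected():
    model = tiny_model()
    fs = derive_feature_sets(model)
    prom = fs.features["promoter"]["chr1"]
    assert [32_000, 37_000] in prom.tolist()  # downstream-side of gB's TSS
    assert [5_000, 10_000] in prom.tolist()


def test_shores_flank_but_exclude_islands():
    fs = derive_feature_sets(tiny_model())
    shores = fs.features["island_shore"]["chr1"].tolist()
    assert shores == [[4_800, 9_800], [10_300, 15_300]]


def test_intron_exon_partition_is_disjoint_and_covers_transcripts():
    fs = derive_feature_sets(tiny_model())
    probes = np.arange(9_000, 33_000, 37)
    in_exon = fs.membership(np.array(["chr1"] * len(probes)), probes, "exon")
    in_intron = fs.membership(np.array(["chr1"] * len(probes)), probes, "intron")
    in_tx = fs.membership(np.array(["chr1"] * len(probes)), probes, "transcript")
    assert not np.any(in_exon & in_intron)
    assert np.array_equal(in_exon | in_intron, in_tx)


def test_intergenic_excludes_gene_proximal_space():
    fs = derive_feature_sets(tiny_model())
    chrom = np.array(["chr1"] * 3)
    probes = np.array([11_000, 60_000, 95_000])  # in-gene, <50 kb away, far
    member = fs.membership(chrom, probes, "intergenic")
    assert member.tolist() == [False, False, True]


def test_membership_matches_naive_interval_scan():
    rng = np.random.default_rng(3)
    cfg = null_config(3)
    model = simulate_annotation(cfg)
    fs = derive_feature_sets(model)
    probes = rng.integers(0, cfg.chrom_length, 1000)
    chrom = np.array(["chr1"] * 1000)
    for label in fs.labels():
        iv = fs.features[label]["chr1"]
        fast = fs.membership(chrom, probes, label)
        naive = np.array([any(s <= p < e for s, e in iv) for p in probes])
        assert np.array_equal(fast, naive)


def test_promoter_clamped_at_chromosome_start():
    tx = [Transcript("g", "chr1", 2_000, 4_000, "+", 2_000, ((2_000, 4_000),))]
    model = GenomeModel({"chr1": 10_000}, tx, [], np.array(["chr1"]),
                        np.array([100]))
    fs = derive_feature_sets(model, promoter_bp=5_000)
    assert fs.features["promoter"]["chr1"].tolist() == [[0, 2_000]]


# ---------------------------------------------------------------------------
# feature enrichment


def test_enrichment_closed_form_all_dml_in_small_feature():
    """All DMLs inside a feature holding 10% of sites → log2 ratio
    log2(10)."""
    n = 1000
    chrom = np.array(["chr1"] * n)
    pos = np.arange(n) * 100
    model = GenomeModel(
        {"chr1": 200_000},
        [Transcript("g", "chr1", 0, 10_000, "+", 0, ((0, 10_000),))],
        [], chrom, pos)
    fs = derive_feature_sets(model)
    # feature 'transcript' covers positions < 10_000: first 100 sites
    dml_idx = np.arange(30)
    enr = feature_enrichment(chrom[dml_idx], pos[dml_idx], chrom, pos, fs)
    assert enr.loc["transcript", "log2_ratio"] == pytest.approx(math.log2(10))


def test_enrichment_null_calibration():
    """DMLs drawn uniformly from all sites: small |log2 ratio| and
    unremarkable p for every feature in most seeds."""
    cfg = null_config(19)
    model = simulate_annotation(cfg)
    fs = derive_feature_sets(model)
    ok = 0
    for seed in range(10):
        rng = np.random.default_rng(seed)
        idx = rng.choice(model.n_sites, 400, replace=False)
        enr = feature_enrichment(model.cpg_chrom[idx], model.cpg_pos[idx],
                                 model.cpg_chrom, model.cpg_pos, fs)
        good = ((enr.log2_ratio.abs() < 0.3) & (enr.p > 0.01)).all()
        ok += bool(good)
    assert ok >= 8


def test_fisher_matches_enumeration_for_tiny_tables():
    """Two-sided Fisher p equals exhaustive enumeration for N <= 20."""
    def enum_fisher(a, b, c, d):
        # enumerate all tables with the same margins, sum probabilities
        # no larger than the observed table's
        n = a + b + c + d
        r1, c1 = a + b, a + c
        def prob(x):
            return (math.comb(r1, x) * math.comb(n - r1, c1 - x)
                    / math.comb(n, c1))
        p_obs = prob(a)
        return sum(prob(x) for x in range(max(0, c1 - (n - r1)),
                                          min(r1, c1) + 1)
                   if prob(x) <= p_obs * (1 + 1e-9))

    rng = np.random.default_rng(7)
    for _ in range(60):
        a, b, c, d = rng.integers(0, 6, 4)
        if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
            continue
        _, p = stats.fisher_exact([[a, b], [c, d]])
        assert p == pytest.approx(enum_fisher(a, b, c, d), abs=1e-9)


# ---------------------------------------------------------------------------
# TSS-distance analyses


def test_signed_distance_strand_orientation():
    model = tiny_model()
    chrom = np.array(["chr1"] * 4)
    pos = np.array([9_900, 10_100, 31_900, 32_100])
    d = signed_tss_distance(chrom, pos, model)
    assert d[0] == -100   # upstream of plus-strand TSS at 10_000
    assert d[1] == 100    # downstream
    assert d[2] == 100    # 31_900 is downstream of minus-strand TSS 32_000
    assert d[3] == -100   # beyond the minus-strand TSS → upstream


def test_window_enrichment_all_null():
    d = np.array([-900, -400, 100, 600, 1_100])
    dml = np.zeros(5, bool)
    res = tss_window_enrichment(d, dml, window_bp=1000, step_bp=500,
                                max_dist=2000)
    assert (res["p"] == 1.0).all()
    assert (res["p_holm"] == 1.0).all()


def test_holm_closed_form():
    from statsmodels.stats.multitest import multipletests

    adj = multipletests([0.01, 0.04], method="holm")[1]
    assert adj == pytest.approx([0.02, 0.04])


def test_planted_upstream_excess_is_top_window():
    rng = np.random.default_rng(9)
    d = rng.integers(-5000, 5000, 4000)
    dml = rng.random(4000) < 0.01
    upstream = (d >= -1000) & (d < 0)
    dml[upstream] |= rng.random(upstream.sum()) < 0.15
    res = tss_window_enrichment(d, dml, window_bp=1000, step_bp=500)
    best = res.loc[res["p_holm"].idxmin()]
    assert -1500 <= best.window_start <= -1000
    assert best["p_holm"] == res["p_holm"].min()


def test_distance_profile_constant_and_oracle():
    d = np.array([-50, -50, 0, 10, 10, 200])
    stat = np.full(6, 3.0)
    prof = distance_stat_profile(d, stat, bandwidth=25.0)
    assert prof["mean_stat"].to_numpy() == pytest.approx(3.0)
    assert prof["smoothed"].to_numpy() == pytest.approx(3.0)
    # group-by oracle on random data
    rng = np.random.default_rng(11)
    d = rng.integers(-300, 300, 500)
    stat = rng.random(500)
    prof = distance_stat_profile(d, stat, bandwidth=50.0)
    oracle = pd.DataFrame({"d": d, "s": stat}).groupby("d")["s"].mean()
    got = prof.set_index("dist")["mean_stat"]
    assert got.to_numpy() == pytest.approx(oracle.loc[got.index].to_numpy())


def test_distance_profile_rejects_nonfinite():
    with pytest.raises(ValueError):
        distance_stat_profile(np.array([0, 1]), np.array([1.0, np.inf]))


# ---------------------------------------------------------------------------
# nested windows


def test_single_cpg_window_mean():
    model = tiny_model()
    # one covered CpG at 100 bp upstream of gA's TSS with level 0.5
    t = np.full((4, 1), 20)
    m = np.full((4, 1), 10)
    table = make_table(m, t, pos=np.array([9_900]))
    mat = nested_window_methylation(table, model, extents=(2400,))
    assert mat.loc[:, -2400].to_numpy() == pytest.approx(0.5)


def test_widening_extent_only_adds_sites():
    cfg = null_config(23)
    model = simulate_annotation(cfg)
    table, _ = simulate_methylome(model, cfg)
    table = filter_by_coverage(table, 10)
    mat = nested_window_methylation(table, model, extents=(600, 4800))
    from permdiff.context import _window_site_indices

    s_small, _ = _window_site_indices(table, model, "upstream", 600)
    s_big, _ = _window_site_indices(table, model, "upstream", 4800)
    assert set(s_small) <= set(s_big)


def test_window_matrix_matches_bruteforce_assignment():
    cfg = null_config(29, n_transcripts=10, chrom_length=300_000)
    model = simulate_annotation(cfg)
    table, _ = simulate_methylome(model, cfg)
    table = filter_by_coverage(table, 10)
    extent = 1200
    mat = nested_window_methylation(table, model, extents=(extent,))
    levels = table.levels()
    # brute force: one occurrence per (site, TSS) pair within the window
    occ = []
    for t in model.transcripts:
        for j in range(table.n_sites):
            if table.chrom[j] != t.chrom:
                continue
            oriented = (table.pos[j] - t.tss) * (1 if t.strand == "+" else -1)
            if -extent <= oriented < 0:
                occ.append(j)
    expected = levels[:, occ].mean(axis=1)
    assert mat.loc[:, -extent].to_numpy() == pytest.approx(expected)


# ---------------------------------------------------------------------------
# PCA segregation


def test_pca_matches_covariance_eigendecomposition():
    rng = np.random.default_rng(31)
    X = pd.DataFrame(rng.normal(0, 1, (12, 40)),
                     index=[f"s{i}" for i in range(12)])
    groups = {f"s{i}": ("control" if i < 6 else "low1C") for i in range(12)}
    res = pca_group_segregation(X, groups)
    centred = X.to_numpy() - X.to_numpy().mean(axis=0)
    cov = centred.T @ centred / (len(X) - 1)
    eigvals = np.linalg.eigvalsh(cov)
    top_var = eigvals[-1]
    pc1_var = res.pc1_scores.to_numpy().var(ddof=1)
    assert pc1_var == pytest.approx(top_var, rel=1e-8)
    # no unit direction explains more variance than PC1
    for _ in range(50):
        u = rng.normal(0, 1, 40)
        u /= np.linalg.norm(u)
        assert (centred @ u).var(ddof=1) <= pc1_var * (1 + 1e-9)


def test_complete_separation_exact_mwu_p():
    """Disjoint constant group profiles: separated, and the exact
    two-sided Mann-Whitney p for complete 6 vs 6 separation is
    2 / C(12,6)."""
    rng = np.random.default_rng(33)
    base = rng.normal(0, 0.01, (12, 5))
    base[6:] += 1.0
    X = pd.DataFrame(base, index=[f"s{i}" for i in range(12)])
    groups = {f"s{i}": ("control" if i < 6 else "low1C") for i in range(12)}
    res = pca_group_segregation(X, groups)
    assert res.separated
    assert res.mwu_p == pytest.approx(2 / math.comb(12, 6))


def test_constant_matrix_rejected():
    X = pd.DataFrame(np.ones((8, 4)), index=[f"s{i}" for i in range(8)])
    groups = {f"s{i}": ("control" if i < 4 else "low1C") for i in range(8)}
    with pytest.raises(ValueError):
        pca_group_segregation(X, groups)


def test_null_separation_rate_near_alpha():
    """Group-exchangeable data: windows rarely separate by chance."""
    hits = 0
    n_seeds = 15
    rng = np.random.default_rng(35)
    groups = {f"s{i}": ("control" if i < 6 else "low1C") for i in range(12)}
    for _ in range(n_seeds):
        X = pd.DataFrame(rng.normal(0, 1, (12, 30)),
                         index=[f"s{i}" for i in range(12)])
        res = pca_group_segregation(X, groups)
        hits += res.separated and res.t_p < 0.05
    # complete separation of 6v6 by chance has probability 2/924 per PCA
    assert hits <= 2


def test_planted_upstream_shift_separates_upstream_windows():
    """A 0.1 methylation shift confined to 1600-4800 bp upstream windows
    separates upstream PCAs but not downstream-only ones."""
    cfg = SimulationConfig(seed=37, n_chroms=1, chrom_length=1_600_000,
                           n_transcripts=40, n_islands=25, n_true_dml=0,
                           n_true_deg=0, tss_band_shift=0.1)
    model = simulate_annotation(cfg)
    table, _ = simulate_methylome(model, cfg)
    seg = nested_window_segregation(filter_by_coverage(table, 10), model)
    upstream = seg.loc[[w for w in seg.index if w < -1200]]
    downstream = seg.loc[[w for w in seg.index if w > 0]]
    assert ((upstream.separated) & (upstream.t_p < 0.05)).any()
    assert (downstream.separated & (downstream.t_p < 0.05)).sum() <= 1


# ---------------------------------------------------------------------------
# nearest genes


def test_nearest_gene_cases():
    genes = pd.DataFrame({
        "chrom": ["chr1", "chr1", "chr2"],
        "start": [1_000, 50_000, 500],
        "end": [2_000, 60_000, 900],
        "gene_id": ["gA", "gB", "gC"],
    })
    regions = pd.DataFrame({
        "chrom": ["chr1", "chr1", "chr1"],
        "start": [1_500, 90_000, 150_000],
        "end": [1_600, 90_100, 150_100],
    })
    res = nearest_gene_assignment(regions, genes, max_dist=40_000)
    assert res.gene_id.tolist() == ["gA", "gB", None]
    assert res.distance.tolist()[:2] == [0, 30_000]


def test_nearest_gene_tie_breaks_to_smaller_start():
    genes = pd.DataFrame({
        "chrom": ["chr1", "chr1"],
        "start": [0, 2_000],
        "end": [500, 2_500],
        "gene_id": ["left", "right"],
    })
    regions = pd.DataFrame({"chrom": ["chr1"], "start": [1_200], "end": [1_300]})
    res = nearest_gene_assignment(regions, genes)
    assert res.gene_id.iloc[0] == "left"  # equidistant (700 bp each side)


def test_nearest_gene_matches_allpairs_oracle():
    rng = np.random.default_rng(41)
    genes = pd.DataFrame({
        "chrom": ["chr1"] * 20,
        "start": np.sort(rng.choice(np.arange(0, 500_000, 100), 20,
                                    replace=False)),
        "gene_id": [f"g{i}" for i in range(20)],
    })
    genes["end"] = genes["start"] + rng.integers(500, 5_000, 20)
    regions = pd.DataFrame({
        "chrom": ["chr1"] * 30,
        "start": rng.integers(0, 500_000, 30),
    })
    regions["end"] = regions["start"] + 100
    res = nearest_gene_assignment(regions, genes, max_dist=40_000)
    for i, r in regions.iterrows():
        dists = np.maximum(
            np.maximum(genes.start - r.end, r.start - genes.end), 0)
        best = dists.min()
        expected = None
        if best <= 40_000:
            cands = genes[dists == best]
            expected = cands.sort_values("start").gene_id.iloc[0]
        assert res.gene_id.iloc[i] == expected


# ---------------------------------------------------------------------------
# methylation–expression association


def test_association_degenerate_constant_methylation():
    meth = pd.DataFrame(np.full((10, 4), 0.5),
                        index=[f"g{i}" for i in range(10)])
    expr = pd.DataFrame(np.random.default_rng(0).random((10, 4)) * 10,
                        index=[f"g{i}" for i in range(10)])
    res = promoter_meth_expr_association(meth, expr)
    assert res.degenerate
    assert res.rho == 0.0


def test_association_requires_three_genes():
    meth = pd.DataFrame(np.random.default_rng(1).random((2, 4)),
                        index=["a", "b"])
    with pytest.raises(ValueError):
        promoter_meth_expr_association(meth, meth)


def test_association_recovers_planted_negative_correlation():
    """Planted rank correlation of -0.5 between promoter methylation and
    expression is recovered within ±0.15 at 500 genes."""
    rng = np.random.default_rng(43)
    n = 500
    z = rng.normal(0, 1, n)
    meth_mean = stats.norm.cdf(0.5 * -z + math.sqrt(1 - 0.25) * rng.normal(0, 1, n))
    expr_mean = np.exp2(2 + z)
    meth = pd.DataFrame({"s1": meth_mean, "s2": meth_mean},
                        index=[f"g{i}" for i in range(n)])
    expr = pd.DataFrame({"s1": expr_mean, "s2": expr_mean},
                        index=[f"g{i}" for i in range(n)])
    res = promoter_meth_expr_association(meth, expr, n_perm=199, seed=0)
    assert res.rho == pytest.approx(-0.5, abs=0.15)
    assert res.p_perm < 0.05


def test_association_matches_rank_oracle_small():
    rng = np.random.default_rng(47)
    n = 30
    meth = pd.DataFrame(rng.random((n, 3)), index=[f"g{i}" for i in range(n)])
    expr = pd.DataFrame(rng.random((n, 3)) * 50,
                        index=[f"g{i}" for i in range(n)])
    res = promoter_meth_expr_association(meth, expr, n_perm=99, seed=1)
    x = meth.mean(axis=1)
    y = np.log2(expr.mean(axis=1) + 1)
    rho_oracle = stats.pearsonr(x.rank(), y.rank()).statistic
    assert res.rho == pytest.approx(rho_oracle, abs=1e-10)


def test_promoter_methylation_extraction():
    model = tiny_model()
    # sites: 5_000 (gA promoter w/ promoter_bp 5000? gA TSS 10_000 → [5_000,10_000): yes),
    # 9_900 (gA promoter), 10_100/10_900 (gene body), 31_000 (gB body),
    # 33_000 (gB promoter [32_000, 37_000)), 150_000 (nothing)
    t = np.full((4, 7), 20)
    m = (np.full((4, 7), 10)).astype(int)
    table = make_table(m, t, pos=np.array([5_000, 9_900, 10_100, 10_900,
                                           31_000, 33_000, 150_000]))
    pm = promoter_methylation(table, model, promoter_bp=5_000)
    assert set(pm.index) == {"gA", "gB"}
    assert pm.loc["gA"].to_numpy() == pytest.approx(0.5)
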