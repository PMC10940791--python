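"""FST estimator against an independent oracle, windows, PCA, LD decay."""

import numpy as np
import pandas as pd
import pytest

import svpopgen as sp
from svpopgen.popgen import wc_fst_components


# ---------------------------------------------------------------------------
# independent scalar transcription of the Weir & Cockerham (1984) estimator
# ---------------------------------------------------------------------------

def wc_oracle(genotypes, labels):
    """Two-population variance components, written from the published
    formulas with explicit loops; independent of the vectorized path."""
    pops = sorted(set(labels))
    assert len(pops) == 2
    n, p, h = [], [], []
    for pop in pops:
        g = [x for x, l in zip(genotypes, labels) if l == pop and x >= 0]
        n_i = len(g)
        n.append(n_i)
        p.append(sum(g) / (2 * n_i))
        h.append(sum(1 for x in g if x == 1) / n_i)
    r = 2
    nbar = sum(n) / r
    nc = (r * nbar - sum(x * x for x in n) / (r * nbar)) / (r - 1)
    pbar = sum(ni * pi for ni, pi in zip(n, p)) / (r * nbar)
    s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * nbar)
    hbar = sum(ni * hi for ni, hi in zip(n, h)) / (r * nbar)
    a = (nbar / nc) * (s2 - (1 / (nbar - 1))
                       * (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - s2 * (r - 1) / r
                               - hbar * (2 * nbar - 1) / (4 * nbar))
    c = hbar / 2
    return a, b, c


def genotypes_from_counts(counts_by_pop):
    """counts_by_pop: list of (n_homref, n_het, n_homalt) per population."""
    genotypes, labels = [], []
    for k, (n0, n1, n2) in enumerate(counts_by_pop):
        genotypes += [0] * n0 + [1] * n1 + [2] * n2
        labels += [f"pop{k}"] * (n0 + n1 + n2)
    return genotypes, labels


def test_fixed_difference_gives_fst_one():
    g, l = genotypes_from_counts([(15, 0, 0), (0, 0, 15)])
    a, b, c, fst = sp.wc_fst_per_variant(g, l)
    assert fst == pytest.approx(1.0)
    assert b == pytest.approx(0.0) and c == pytest.approx(0.0)


def test_identical_populations_give_zero():
    g, l = genotypes_from_counts([(5, 10, 5), (5, 10, 5)])
    a, b, c, fst = sp.wc_fst_per_variant(g, l)
    assert a <= 0 and fst <= 0   # estimator may be slightly negative


def test_monomorphic_reported_as_zero_with_flag():
    g, l = genotypes_from_counts([(10, 0, 0), (12, 0, 0)])
    comp = wc_fst_components(np.array(g).reshape(-1, 1), l)
    assert comp.monomorphic[0]
    assert comp.fst[0] == 0.0


def test_undefined_when_population_too_small():
    g = np.array([0, 1, 2, -1, -1, 1]).reshape(-1, 1)
    labels = ["A", "A", "A", "B", "B", "B"]   # pop B: 1 non-missing
    comp = wc_fst_components(g, labels)
    assert not comp.defined[0] and np.isnan(comp.fst[0])


@pytest.mark.parametrize("counts", [
    [(5, 10, 5), (14, 2, 0)],
    [(20, 5, 4), (1, 10, 19)],
    [(29, 0, 0), (11, 10, 10)],
])
def test_components_match_oracle(counts):
    g, l = genotypes_from_counts(counts)
    a, b, c, fst = sp.wc_fst_per_variant(g, l)
    oa, ob, oc = wc_oracle(g, l)
    assert a == pytest.approx(oa, abs=1e-12)
    assert b == pytest.approx(ob, abs=1e-12)
    assert c == pytest.approx(oc, abs=1e-12)
    assert fst == pytest.approx(oa / (oa + ob + oc), abs=1e-12)


def test_components_match_oracle_with_missingness(rng):
    for _ in range(50):
        g = rng.integers(0, 3, size=40)
        g[rng.random(40) < 0.2] = -1
        labels = ["A"] * 19 + ["B"] * 21
        if min((g[:19] >= 0).sum(), (g[19:] >= 0).sum()) < 2:
            continue
        comp = wc_fst_components(g.reshape(-1, 1), labels)
        if comp.monomorphic[0]:
            continue
        oa, ob, oc = wc_oracle(list(g), labels)
        assert comp.a[0] == pytest.approx(oa, abs=1e-12)
        assert comp.b[0] == pytest.approx(ob, abs=1e-12)
        assert comp.c[0] == pytest.approx(oc, abs=1e-12)


# ---------------------------------------------------------------------------
# weighted FST
# ---------------------------------------------------------------------------

def test_weighted_fst_is_ratio_of_sums():
    from svpopgen.popgen import FstComponents
    comp = FstComponents(
        a=np.array([1.0, 0.0]), b=np.array([0.0, 0.0]), c=np.array([1.0, 1.0]),
        fst=np.array([0.5, 0.0]), defined=np.array([True, True]),
        monomorphic=np.array([False, False]))
    # ratio of sums (1+0)/(2+1) = 1/3, not the mean of ratios 1/4
    assert sp.weighted_fst(components=comp) == pytest.approx(1 / 3)


def test_weighted_fst_single_variant_and_reorder(snp_matrix):
    comp = wc_fst_components(snp_matrix.matrix, snp_matrix.populations)
    j = int(np.flatnonzero(comp.defined)[0])
    single = snp_matrix.subset_variants(np.arange(snp_matrix.n_variants) == j)
    assert sp.weighted_fst(single) == pytest.approx(comp.fst[j])
    rng = np.random.default_rng(0)
    perm = rng.permutation(snp_matrix.n_variants)
    reordered = snp_matrix.subset_variants(np.isin(np.arange(snp_matrix.n_variants), perm))
    assert sp.weighted_fst(snp_matrix) == sp.weighted_fst(reordered)


def test_weighted_fst_empty_scope(snp_matrix):
    assert np.isnan(sp.weighted_fst(snp_matrix,
                                    mask=np.zeros(snp_matrix.n_variants, bool)))


# ---------------------------------------------------------------------------
# windows
# ---------------------------------------------------------------------------

def test_all_variants_in_one_window_equals_genome_fst(snp_matrix):
    gm = snp_matrix
    meta = gm.variants.copy()
    meta["pos"] = np.arange(1, gm.n_variants + 1) * 10 + 1   # all inside 100 kb
    meta["chrom"] = "chr1"
    gm2 = sp.GenotypeMatrix(gm.samples, gm.populations, gm.matrix, meta)
    win = sp.sliding_window_fst(gm2, chrom_lengths={"chr1": 100_000})
    full = win[win["start"] == 0].iloc[0]
    assert full["fst"] == pytest.approx(sp.weighted_fst(gm2))


def test_window_membership_half_open_boundary(snp_matrix):
    """A variant at 0-based position 100,000 belongs exactly to the sliding
    windows starting 10,000..100,000."""
    gm = snp_matrix
    meta = gm.variants.iloc[:1].copy()
    meta["pos"] = 100_001          # VCF 1-based -> 0-based 100,000
    meta["chrom"] = "chr1"
    gm1 = sp.GenotypeMatrix(gm.samples, gm.populations, gm.matrix[:, :1], meta)
    win = sp.sliding_window_fst(gm1, chrom_lengths={"chr1": 200_001})
    with_var = set(win.loc[win["n_variants"] == 1, "start"])
    assert with_var == set(range(10_000, 100_001, 10_000))


def test_planted_divergence_cluster_is_local_maximum(small_config):
    cfg = sp.SimConfig(seed=13, n_snps=2_000, n_indels=0, n_svs=0,
                       chrom_lengths={"chr1": 1_000_000}, divergent_frac=0.0)
    truth = sp.simulate_frequencies(cfg)
    # plant a tight strongly divergent cluster around 500 kb
    loci = truth.loci
    in_cluster = (loci["pos"] >= 500_000) & (loci["pos"] < 520_000)
    loci.loc[in_cluster, "p1"] = 0.95
    loci.loc[in_cluster, "p2"] = 0.05
    gm = sp.simulate_genotypes(truth, cfg).matrix("SNP")
    win = sp.sliding_window_fst(gm, chrom_lengths={"chr1": 1_000_000})
    peak = win.loc[win["fst"].idxmax()]
    assert 420_000 <= peak["start"] <= 520_000


def test_step_larger_than_window_warns(snp_matrix):
    with pytest.warns(UserWarning):
        sp.sliding_window_fst(snp_matrix, window=1000, step=5000,
                              chrom_lengths={c: 10_000 for c in
                                             set(snp_matrix.variants["chrom"])})


# ---------------------------------------------------------------------------
# bp covered per window
# ---------------------------------------------------------------------------

def test_large_deletion_covers_094_of_window():
    variants = pd.DataFrame({
        "chrom": ["chr1"], "pos": [3001], "end": [3000 + 94_100],
        "length": [94_100], "svtype": ["DEL"],
    })
    track = sp.bp_covered_per_window(variants, chrom_lengths={"chr1": 100_000})
    assert track.loc[0, "bp_covered_fraction"] == pytest.approx(0.941, abs=1e-3)


def test_snps_count_one_bp_each():
    variants = pd.DataFrame({
        "chrom": ["chr1"] * 7, "pos": np.arange(100, 800, 100),
        "end": np.arange(100, 800, 100), "length": [1] * 7,
        "svtype": [None] * 7,
    })
    track = sp.bp_covered_per_window(variants, chrom_lengths={"chr1": 100_000})
    assert track.loc[0, "bp_covered"] == 7
    assert track.loc[0, "bp_covered_fraction"] == pytest.approx(7 / 100_000)


def test_insertion_assigned_to_anchor_window_and_capped():
    variants = pd.DataFrame({
        "chrom": ["chr1"], "pos": [150_000], "end": [150_000],
        "length": [500_000], "svtype": ["INS"],
    })
    track = sp.bp_covered_per_window(variants, chrom_lengths={"chr1": 300_000})
    assert track.loc[1, "bp_covered"] == 500_000
    assert track.loc[1, "bp_covered_fraction"] == 1.0      # capped
    assert track.loc[0, "bp_covered"] == 0


def test_deletion_spanning_windows_split():
    variants = pd.DataFrame({
        "chrom": ["chr1"], "pos": [90_001], "end": [110_000],
        "length": [20_000], "svtype": ["DEL"],
    })
    track = sp.bp_covered_per_window(variants, chrom_lengths={"chr1": 200_000})
    assert track.loc[0, "bp_covered"] == 10_000
    assert track.loc[1, "bp_covered"] == 10_000


def test_genome_totals_match_truth_bookkeeping(small_truth, small_sim):
    """Summed per-window bp equals the truth's per-class length totals."""
    gm = small_sim.matrix("SV")
    track = sp.bp_covered_per_window(
        gm.variants, chrom_lengths={"chr1": 2_000_000, "chr2": 2_000_000})
    svs = small_truth.svs
    expected = svs["length"].sum()
    assert track["bp_covered"].sum() == expected


def test_overlap_union_not_double_counting():
    variants = pd.DataFrame({
        "chrom": ["chr1", "chr1"], "pos": [1001, 1001], "end": [2000, 2000],
        "length": [1000, 1000], "svtype": ["DEL", "DEL"],
    })
    summed = sp.bp_covered_per_window(variants, chrom_lengths={"chr1": 100_000})
    union = sp.bp_covered_per_window(variants, chrom_lengths={"chr1": 100_000},
                                     overlap_union=True)
    assert summed.loc[0, "bp_covered"] == 2000
    assert union.loc[0, "bp_covered"] == 1000


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def test_pca_two_clone_groups():
    rng = np.random.default_rng(3)
    a = rng.integers(0, 3, size=50)
    b = rng.integers(0, 3, size=50)
    g = np.vstack([np.tile(a, (10, 1)), np.tile(b, (10, 1))])
    res = sp.pca(g)
    assert res.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-9)
    pc1 = res.scores[:, 0]
    assert (pc1[:10] > 0).all() != (pc1[10:] > 0).all()    # separated groups


def test_pca_separates_populations(snp_matrix):
    cfg = sp.SimConfig(seed=21, n_snps=3_000, n_indels=0, n_svs=0,
                       theta_fst=0.05, divergent_frac=0.05)
    gm = sp.simulate_genotypes(sp.simulate_frequencies(cfg), cfg).matrix("SNP")
    res = sp.pca(gm)
    pc1 = res.scores[:, 0]
    lab = gm.populations
    m1, m2 = pc1[lab == "RO"], pc1[lab == "PU"]
    assert max(m1.min(), m2.min()) > min(m1.max(), m2.max()) or \
           max(m2.min(), m1.min()) > min(m2.max(), m1.max()) or \
           (m1.max() < m2.min() or m2.max() < m1.min())


def test_pca_eigenvalues_match_svd_oracle(snp_matrix):
    """Eigenvalues agree with an independent SVD of the standardized matrix."""
    gm = snp_matrix
    res = sp.pca(gm)
    x = gm.matrix.astype(float)
    x[x == sp.GT_MISSING] = np.nan
    mean = np.nanmean(x, axis=0)
    idx = np.where(np.isnan(x))
    x[idx] = mean[idx[1]]
    p = mean / 2
    scale = np.sqrt(p * (1 - p))
    keep = scale > 0
    x = (x[:, keep] - mean[keep]) / scale[keep]
    sv = np.linalg.svd(x, compute_uv=False)
    oracle = sv ** 2 / x.shape[1]
    np.testing.assert_allclose(res.eigenvalues, oracle[:len(res.eigenvalues)],
                               atol=1e-8)


def test_pca_scores_orthogonal(snp_matrix):
    res = sp.pca(snp_matrix)
    gram = res.eigenvectors.T @ res.eigenvectors
    np.testing.assert_allclose(gram, np.eye(gram.shape[0]), atol=1e-8)


def test_pca_rejects_degenerate():
    with pytest.raises(ValueError):
        sp.pca(np.zeros((5, 4), dtype=np.int8))
    with pytest.raises(ValueError):
        sp.pca(np.array([[0, 1, 2]], dtype=np.int8))


# ---------------------------------------------------------------------------
# track correlation
# ---------------------------------------------------------------------------

def test_track_correlation_identity_and_affine(rng):
    a = rng.normal(size=200)
    r2, p = sp.window_track_correlation(a, a)
    assert r2 == pytest.approx(1.0)
    r2, p = sp.window_track_correlation(a, 3.5 * a - 2.0)
    assert r2 == pytest.approx(1.0)
    assert p < 1e-10


def test_track_correlation_independent_tracks(rng):
    r2s = [sp.window_track_correlation(rng.normal(size=1000),
                                       rng.normal(size=1000))[0]
           for _ in range(20)]
    assert np.mean(r2s) < 0.01


def test_track_correlation_undefined_below_three_windows():
    r2, p = sp.window_track_correlation(np.array([1.0, 2.0, np.nan]),
                                        np.array([1.0, 2.0, 3.0]))
    assert np.isnan(r2) and np.isnan(p)


# ---------------------------------------------------------------------------
# LD decay
# ---------------------------------------------------------------------------

def _matrix_from_genotypes(g, positions, samples_prefix="s"):
    n = g.shape[0]
    samples = [f"{samples_prefix}{i}" for i in range(n)]
    popmap = {s: ("A" if i < n // 2 else "B") for i, s in enumerate(samples)}
    meta = pd.DataFrame({
        "chrom": ["chr1"] * g.shape[1], "pos": positions,
        "id": [f"v{j}" for j in range(g.shape[1])],
        "vclass": ["SNP"] * g.shape[1], "length": [1] * g.shape[1],
        "end": positions, "svtype": [None] * g.shape[1],
    })
    return sp.GenotypeMatrix(samples, np.array([popmap[s] for s in samples]),
                             g.astype(np.int8), meta)


def test_ld_duplicated_column_r2_one(rng):
    col = rng.integers(0, 3, size=40)
    g = np.column_stack([col, col])
    gm = _matrix_from_genotypes(g, np.array([1000, 1150]))
    decay = sp.ld_decay(gm, max_dist=500, bin_edges=[0, 100, 200, 500])
    row = decay[(decay["bin_lo"] == 100)].iloc[0]
    assert row["mean_r2"] == pytest.approx(1.0)
    assert row["n_pairs"] == 1


def test_ld_independent_loci_near_bias_floor():
    """Independent loci: E[r^2] ~ 1/(n-1) at n=60."""
    rng = np.random.default_rng(8)
    n, m = 60, 120
    g = rng.binomial(2, 0.5, size=(n, m))
    gm = _matrix_from_genotypes(g, np.arange(m) * 10 + 1)
    decay = sp.ld_decay(gm, max_dist=1_200, bin_edges=[0, 1_200])
    assert decay.loc[0, "mean_r2"] == pytest.approx(1 / (n - 1), rel=0.3)


def test_ld_ar1_haplotypes_decay_monotone():
    rng = np.random.default_rng(4)
    positions = np.sort(rng.choice(np.arange(1, 3000), size=150, replace=False))
    p = np.full(150, 0.5)
    g = sp.simulate_linked_genotypes(80, positions, p, decay_bp=300, rng=rng)
    gm = _matrix_from_genotypes(g, positions)
    decay = sp.ld_decay(gm, max_dist=2_000,
                        bin_edges=[0, 250, 500, 1_000, 2_000])
    r2 = decay["mean_r2"].to_numpy()
    assert (np.diff(r2) < 0).all()
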