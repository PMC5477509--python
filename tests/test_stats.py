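import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from feralgen.errors import ParameterError
from feralgen.io import GenotypeMatrix
from feralgen.stats import (
    SFS,
    SiteCounts,
    build_sfs,
    fold_sfs,
    folded_support,
    mask_singletons,
    observed_het,
    project_sfs,
    read_sfs,
    site_pi,
    tajima_constants,
    tajimas_d,
    wc_fst_window,
    window_observed_het,
    window_pi,
    window_tajimas_d,
    write_sfs,
)
from .conftest import random_genotype_matrix
from .oracles import (
    brute_hypergeom_projection,
    brute_site_pi,
    brute_tajimas_d,
    brute_wc_fst,
    brute_window_pi,
)


# ---------------------------------------------------------------------------
# site pi / H_O
# ---------------------------------------------------------------------------


def test_site_pi_derived_example():
    # j=2 of n=4: all C(4,2)=6 haplotype pairs enumerated, 4 differ -> 2/3
    assert site_pi(SiteCounts(4, 2, 0))[0] == pytest.approx(2 / 3, abs=1e-9)
    assert brute_site_pi([1, 1]) == pytest.approx(2 / 3)


def test_site_pi_monomorphic():
    assert site_pi(SiteCounts(4, 0, 0))[0] == 0.0
    assert site_pi(SiteCounts(4, 4, 0))[0] == 0.0


def test_site_pi_single_pair():
    assert site_pi(SiteCounts(2, 1, 1))[0] == 1.0


@given(st.integers(2, 60), st.data())
def test_site_pi_matches_enumeration(n_alleles, data):
    j = data.draw(st.integers(0, n_alleles))
    got = site_pi(SiteCounts(n_alleles, j, 0))[0]
    expected = 2.0 * j * (n_alleles - j) / (n_alleles * (n_alleles - 1))
    assert got == pytest.approx(expected, abs=1e-12)
    assert 0.0 <= got <= 1.0 + 1e-12


def test_observed_het():
    assert observed_het(SiteCounts(20, 5, 5))[0] == pytest.approx(0.5)
    assert observed_het(SiteCounts(20, 10, 0))[0] == 0.0
    assert observed_het(SiteCounts(20, 10, 10))[0] == 1.0
    assert np.isnan(observed_het(SiteCounts(0, 0, 0))[0])


# ---------------------------------------------------------------------------
# Tajima's D
# ---------------------------------------------------------------------------


def test_tajimas_d_singleton_n4():
    # independent evaluation: a1 = 11/6, e1 = c1/a1 with c1 = b1 - 1/a1
    k = tajima_constants(4)
    assert k.a1 == pytest.approx(11 / 6, abs=1e-12)
    # e1 = c1/a1 with c1 = b1 - 1/a1 = 5/9 - 6/11 = 1/99
    assert k.e1 == pytest.approx((1 / 99) / (11 / 6), abs=1e-12)
    assert tajimas_d(1, 0.5, 4) == pytest.approx(-0.612372, abs=1e-5)


def test_tajimas_d_no_segregating_sites():
    assert np.isnan(tajimas_d(0, 0.0, 10))


def test_tajimas_d_small_n_error():
    with pytest.raises(ParameterError):
        tajimas_d(1, 0.5, 3)


def test_tajimas_d_fold_symmetry(rng):
    # swapping ref/alt labels at every site leaves D unchanged
    m = random_genotype_matrix(rng, n_samples=10, n_sites=300, missing_rate=0.0)
    flipped = m.geno.copy()
    flipped[flipped >= 0] = 2 - flipped[flipped >= 0]
    m2 = GenotypeMatrix(m.samples, m.chrom, m.pos, m.alt, m.ref, flipped)
    windows = [("chr1", 0, 400_000), ("chr2", 0, 300_000)]
    d1 = window_tajimas_d(m, m.samples, windows)
    d2 = window_tajimas_d(m2, m2.samples, windows)
    for a, b in zip(d1, d2):
        assert a.value == pytest.approx(b.value, abs=1e-12)


# ---------------------------------------------------------------------------
# Windowed statistics vs brute force
# ---------------------------------------------------------------------------


def _window_columns(matrix, chrom, start, end):
    idx = [
        i
        for i in range(matrix.n_sites)
        if matrix.chrom[i] == chrom and start <= matrix.pos[i] < end
    ]
    return [matrix.geno[:, i].tolist() for i in idx]


def test_window_pi_derived_example():
    # single constructed site: j=2 of n=4 in a 100 kb window
    g = np.array([[1], [1]], dtype=np.int8)
    mat = GenotypeMatrix(["a", "b"], ["chr1"], [50], ["A"], ["G"], g)
    [w] = window_pi(mat, ["a", "b"], [("chr1", 0, 100_000)])
    assert w.value == pytest.approx(6.6667e-6, rel=1e-4)


def test_window_pi_empty_window(small_matrix):
    [w] = window_pi(small_matrix, small_matrix.samples, [("chrX", 0, 1000)])
    assert w.value == 0.0 and w.n_snps == 0


def test_sliding_windows_share_snps(rng):
    m = random_genotype_matrix(rng, 6, 40, chrom_lengths=(("chr1", 100_000),))
    target = int(m.pos[0])
    w1 = (
        "chr1",
        max(0, target - 5000),
        max(0, target - 5000) + 10_000,
    )
    w2 = ("chr1", max(0, target - 2000), max(0, target - 2000) + 10_000)
    r1 = window_pi(m, m.samples, [w1])[0]
    r2 = window_pi(m, m.samples, [w2])[0]
    assert r1.n_snps >= 1 and r2.n_snps >= 1


def test_windowed_stats_match_brute_force(rng):
    m = random_genotype_matrix(rng, n_samples=14, n_sites=400)
    pop1 = m.samples[:7]
    pop2 = m.samples[7:]
    windows = [
        ("chr1", 0, 100_000),
        ("chr1", 50_000, 150_000),
        ("chr2", 0, 300_000),
    ]
    pis = window_pi(m, m.samples, windows)
    fsts = wc_fst_window(m, pop1, pop2, windows)
    ds = window_tajimas_d(m, m.samples, windows, min_snps=1)
    idx1 = m.sample_indices(pop1)
    idx2 = m.sample_indices(pop2)
    for (chrom, start, end), wp, wf, wd in zip(windows, pis, fsts, ds):
        cols = _window_columns(m, chrom, start, end)
        assert wp.value == pytest.approx(
            brute_window_pi(cols, end - start), abs=1e-12
        )
        cols1 = [[c[i] for i in idx1] for c in cols]
        cols2 = [[c[i] for i in idx2] for c in cols]
        bf = brute_wc_fst(cols1, cols2)
        if np.isnan(bf):
            assert np.isnan(wf.value)
        else:
            assert wf.value == pytest.approx(bf, abs=1e-9)
        bd = brute_tajimas_d(cols)
        if np.isnan(bd):
            assert np.isnan(wd.value)
        else:
            assert wd.value == pytest.approx(bd, abs=1e-9)


def test_wc_fst_fixed_difference():
    g = np.array([[2, 2, 2, 2, 0, 0, 0, 0]], dtype=np.int8).T.reshape(8, 1)
    mat = GenotypeMatrix(
        [f"s{i}" for i in range(8)], ["chr1"], [10], ["A"], ["G"], g
    )
    [w] = wc_fst_window(
        mat, [f"s{i}" for i in range(4)], [f"s{i}" for i in range(4, 8)],
        [("chr1", 0, 100)],
    )
    assert w.value == pytest.approx(1.0, abs=1e-12)


def test_wc_fst_textbook_single_site():
    # p1=0.5 (10 diploids, 5 hets), p2=0.1 (10 diploids, 2 hets): direct
    # scalar transcription of the 1984 variance components
    from feralgen.stats import wc_variance_components

    c1 = SiteCounts(20, 10, 5)
    c2 = SiteCounts(20, 2, 2)
    a, b, c, usable = wc_variance_components(c1, c2)
    n1 = n2 = 10
    nbar = 10.0
    nc = (2 * nbar - (n1**2 + n2**2) / (2 * nbar)) / 1
    pbar = (n1 * 0.5 + n2 * 0.1) / (2 * nbar)
    s2 = (n1 * (0.5 - pbar) ** 2 + n2 * (0.1 - pbar) ** 2) / nbar
    hbar = (n1 * 0.5 + n2 * 0.2) / (2 * nbar)
    a_ref = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - s2 / 2 - hbar / 4) / (nbar - 1)
    )
    b_ref = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - s2 / 2 - hbar * (2 * nbar - 1) / (4 * nbar)
    )
    c_ref = hbar / 2
    assert usable[0]
    assert a[0] == pytest.approx(a_ref, abs=1e-12)
    assert b[0] == pytest.approx(b_ref, abs=1e-12)
    assert c[0] == pytest.approx(c_ref, abs=1e-12)
    # frozen: hand evaluation gives a=0.0708333, b=0.0041667, c=0.175
    assert a[0] / (a[0] + b[0] + c[0]) == pytest.approx(0.28333333, abs=1e-8)


def test_wc_fst_genotype_columns_vs_oracle():
    col1 = [2, 2, 1, 1, 1, 1, 1, 0, 0, 0]
    col2 = [0, 0, 0, 0, 0, 0, 0, 0, 1, 1]
    g = np.array([col1 + col2], dtype=np.int8).T.reshape(20, 1)
    mat = GenotypeMatrix(
        [f"s{i}" for i in range(20)], ["chr1"], [10], ["A"], ["G"], g
    )
    [w] = wc_fst_window(
        mat,
        [f"s{i}" for i in range(10)],
        [f"s{i}" for i in range(10, 20)],
        [("chr1", 0, 100)],
    )
    assert w.value == pytest.approx(brute_wc_fst([col1], [col2]), abs=1e-12)


def test_wc_fst_same_sample_near_zero(rng):
    m = random_genotype_matrix(rng, n_samples=20, n_sites=150, missing_rate=0.0)
    fst = wc_fst_window(
        m, m.samples[:10], m.samples[10:], [("chr1", 0, 400_000), ("chr2", 0, 300_000)]
    )
    vals = [w.value for w in fst if not np.isnan(w.value)]
    assert abs(np.mean(vals)) < 0.05


def test_window_observed_het(rng):
    m = random_genotype_matrix(rng, n_samples=10, n_sites=100)
    [w] = window_observed_het(m, m.samples, [("chr1", 0, 400_000)])
    from .oracles import brute_observed_het

    cols = _window_columns(m, "chr1", 0, 400_000)
    vals = [brute_observed_het(c) for c in cols]
    vals = [v for v in vals if not np.isnan(v)]
    assert w.value == pytest.approx(np.mean(vals), abs=1e-12)


# ---------------------------------------------------------------------------
# SFS
# ---------------------------------------------------------------------------


def test_build_sfs_counts():
    # 3 sites with alt counts 1, 1, 2 in n=4 alleles
    g = np.array([[1, 0, 1], [0, 1, 1]], dtype=np.int8)
    mat = GenotypeMatrix(["a", "b"], ["chr1"] * 3, [1, 2, 3], ["A"] * 3, ["G"] * 3, g)
    sfs = build_sfs(mat, ["a", "b"])
    assert sfs.counts[1] == 2 and sfs.counts[2] == 1


def test_build_sfs_monomorphic_alt():
    g = np.array([[2], [2]], dtype=np.int8)
    mat = GenotypeMatrix(["a", "b"], ["chr1"], [1], ["A"], ["G"], g)
    sfs = build_sfs(mat, ["a", "b"])
    assert sfs.counts[4] == 1


def test_build_sfs_2d():
    g = np.array([[1], [0], [0], [0]], dtype=np.int8)
    mat = GenotypeMatrix(list("abcd"), ["chr1"], [1], ["A"], ["G"], g)
    sfs = build_sfs(mat, ["a", "b"], ["c", "d"])
    assert sfs.dims == 2
    assert sfs.counts[1, 0] == 1


def test_build_sfs_missing_data_projection():
    # site 1 fully called (4 alleles), site 2 half-missing (2 alleles)
    g = np.array([[1, 1], [1, -1]], dtype=np.int8)
    mat = GenotypeMatrix(["a", "b"], ["chr1", "chr1"], [1, 2], ["A"] * 2,
                         ["G"] * 2, g)
    dropped = build_sfs(mat, ["a", "b"])  # no projection: missing site dropped
    assert dropped.total() == 1
    proj = build_sfs(mat, ["a", "b"], project_to=2)
    # both sites contribute hypergeometric mass at n=2; total conserved
    assert proj.total() == pytest.approx(2.0, abs=1e-9)
    # site 2 (j=1 of n=2) lands exactly on counts[1]
    expected_site1 = np.array(brute_hypergeom_projection(2, 4, 2))
    np.testing.assert_allclose(
        proj.counts, expected_site1 + np.array([0, 1, 0]), atol=1e-9
    )


def test_project_sfs_weights():
    # j=2 of n=4 projected to m=2: weights (1/6, 4/6, 1/6)
    sfs = SFS(np.array([0.0, 0, 1, 0, 0]))
    proj = project_sfs(sfs, 2)
    np.testing.assert_allclose(proj.counts, [1 / 6, 4 / 6, 1 / 6], atol=1e-12)
    np.testing.assert_allclose(
        proj.counts, brute_hypergeom_projection(2, 4, 2), atol=1e-12
    )


def test_project_identity_and_conservation(rng):
    counts = rng.integers(0, 50, size=21).astype(float)
    sfs = SFS(counts)
    same = project_sfs(sfs, 20)
    np.testing.assert_allclose(same.counts, counts, atol=1e-9)
    smaller = project_sfs(sfs, 7)
    assert smaller.total() == pytest.approx(sfs.total(), abs=1e-9)


def test_project_up_error():
    with pytest.raises(ParameterError):
        project_sfs(SFS(np.ones(5)), 10)


def test_fold_derived_example():
    folded = fold_sfs(SFS(np.array([0.0, 3, 2, 1, 0])))
    np.testing.assert_allclose(folded.counts, [0, 4, 2, 0, 0], atol=1e-12)
    assert folded.folded


def test_fold_idempotent(rng):
    sfs = SFS(rng.integers(0, 20, size=12).astype(float))
    once = fold_sfs(sfs)
    twice = fold_sfs(once)
    np.testing.assert_allclose(once.counts, twice.counts)


def test_fold_conserves_mass_2d(rng):
    counts = rng.integers(0, 10, size=(9, 7)).astype(float)
    sfs = SFS(counts)
    folded = fold_sfs(sfs)
    assert folded.total() == pytest.approx(sfs.total(), abs=1e-9)
    assert not folded.counts[~folded_support(folded.counts.shape)].any()


def test_mask_singletons_1d():
    sfs = mask_singletons(SFS(np.array([5.0, 4, 3, 2, 1, 0, 1])))  # n=6
    assert sfs.mask[1] and sfs.mask[5]
    assert not sfs.mask[2] and not sfs.mask[3]
    # masked entries excluded from likelihood sums via unmasked_counts
    assert 4 not in sfs.unmasked_counts()


def test_mask_singletons_2d_total_minor():
    sfs = mask_singletons(SFS(np.ones((5, 5))))  # n1=n2=4, n_tot=8
    assert sfs.mask[0, 1] and sfs.mask[1, 0]
    assert sfs.mask[4, 3] and sfs.mask[3, 4]
    assert not sfs.mask[1, 1]


@given(st.integers(4, 30), st.integers(2, 20))
@settings(max_examples=25, deadline=None)
def test_projection_conserves_mass_property(n, m):
    if m > n:
        n, m = m, n
    rng = np.random.default_rng(n * 31 + m)
    sfs = SFS(rng.random(n + 1) * 10)
    proj = project_sfs(sfs, m)
    assert proj.total() == pytest.approx(sfs.total(), rel=1e-9)
    assert (proj.counts >= -1e-12).all()


def test_sfs_round_trip(tmp_path, rng):
    counts = rng.integers(0, 30, size=(11, 9)).astype(float)
    sfs = mask_singletons(fold_sfs(SFS(counts)))
    write_sfs(sfs, tmp_path / "s.tsv", tmp_path / "s.json")
    back = read_sfs(tmp_path / "s.tsv", tmp_path / "s.json")
    np.testing.assert_allclose(back.counts, sfs.counts)
    np.testing.assert_array_equal(back.mask, sfs.mask)
    assert back.folded == sfs.folded
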