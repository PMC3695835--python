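"""QC, kinship, LD pruning, F_ST, PCA and the admixture EM model."""

import numpy as np
import pytest

from arcticpop import autosomal as au
from arcticpop import synthdata
from arcticpop.core import GenotypeMatrix, InvalidArgument, MISSING


def make_gm(calls, pops=None, chroms=None):
    calls = np.asarray(calls, dtype=np.int8)
    n, L = calls.shape
    return GenotypeMatrix(
        calls=calls,
        sample_ids=[f"S{i}" for i in range(n)],
        populations=pops or ["P"] * n,
        snp_ids=[f"snp{j}" for j in range(L)],
        chromosomes=np.asarray(chroms) if chroms is not None
        else np.ones(L, dtype=int),
        positions=np.arange(1, L + 1) * 100,
    )


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def test_qc_removes_monomorphic():
    gm = make_gm([[0, 1], [0, 1], [0, 0], [0, 2]])
    out, rep = au.qc_filter(gm, return_report=True)
    assert out.snp_ids == ["snp1"]
    assert rep.n_removed_maf == 1


def test_qc_call_rate_strict_threshold():
    calls = np.ones((100, 1), dtype=np.int8)
    calls[:50, 0] = 0
    calls[:4, 0] = MISSING  # call rate 0.96 < 0.97
    out = au.qc_filter(make_gm(calls))
    assert out.n_snps == 0


def test_qc_keeps_good_snp_and_drops_non_autosomal():
    calls = np.tile([0, 1, 2, 1], (4, 1)).T  # MAF 0.5, full calls
    gm = make_gm(calls, chroms=[1, 22, 23, 25])
    out, rep = au.qc_filter(make_gm(calls, chroms=[1, 22, 23, 25]),
                            return_report=True)
    assert out.snp_ids == ["snp0", "snp1"]
    assert rep.n_removed_autosome == 2
    assert rep.n_input == rep.n_kept + rep.n_removed_autosome \
        + rep.n_removed_maf + rep.n_removed_call_rate


# ---------------------------------------------------------------------------
# Kinship
# ---------------------------------------------------------------------------

def test_duplicate_sample_kinship_half():
    rng = np.random.default_rng(0)
    row = rng.integers(0, 3, size=500)
    gm = make_gm(np.vstack([row, row]))
    assert au.robust_kinship(gm, 0, 1) == pytest.approx(0.5)


def test_kinship_matrix_agrees_with_pairwise():
    coh = synthdata.sim_admixed_genotypes([10], 400, 1, 0.1, [1.0], seed=3,
                                          missing_rate=0.05)
    gm = coh.genotypes
    phi = au.kinship_matrix(gm)
    for i, j in [(0, 1), (2, 7), (4, 9)]:
        assert phi[i, j] == pytest.approx(au.robust_kinship(gm, i, j))


def test_kinship_undefined_without_overlap():
    calls = np.array([[1, MISSING], [MISSING, 1]])
    with pytest.raises(InvalidArgument):
        au.robust_kinship(make_gm(calls), 0, 1)


def test_remove_relatives_no_pairs_is_identity():
    coh = synthdata.sim_admixed_genotypes([12], 800, 1, 0.1, [1.0], seed=5)
    out = au.remove_relatives(coh.genotypes)
    assert out.n_samples == 12


def test_remove_relatives_drops_one_of_duplicate_pair():
    rng = np.random.default_rng(1)
    base = rng.integers(0, 3, size=(6, 800)).astype(np.int8)
    base[5] = base[0]  # duplicate pair
    out, removed = au.remove_relatives(make_gm(base), return_removed=True)
    assert len(removed) == 1
    assert out.n_samples == 5


def test_remove_relatives_trio_drops_child_first():
    rng = np.random.default_rng(2)
    L = 3000
    p = rng.uniform(0.2, 0.8, size=L)
    mom = rng.binomial(2, p).astype(np.int8)
    dad = rng.binomial(2, p).astype(np.int8)
    child = (rng.binomial(1, mom / 2) + rng.binomial(1, dad / 2)).astype(np.int8)
    gm = make_gm(np.vstack([mom, dad, child]))
    out, removed = au.remove_relatives(gm, return_removed=True)
    assert removed[0] == "S2"  # child has two conflicts, parents one each
    # postcondition: no remaining pair above threshold
    phi = au.kinship_matrix(out)
    np.fill_diagonal(phi, 0.0)
    assert (phi <= au.SECOND_DEGREE_THRESHOLD).all()


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------

def audit_prune(gm, kept_ids, r2_max, window, step):
    """Definitional check: no retained pair within any window exceeds r2."""
    keep_set = set(kept_ids)
    order = np.lexsort((gm.positions, gm.chromosomes))
    kept_pos = [i for i in range(gm.n_snps) if gm.snp_ids[order[i]] in keep_set]
    calls = gm.calls[:, order]
    start = 0
    while start < gm.n_snps:
        idx = [i for i in kept_pos if start <= i < start + window]
        if len(idx) > 1:
            r2 = au._pairwise_r2(calls[:, idx])
            off = r2[np.triu_indices(len(idx), k=1)]
            assert (off <= r2_max + 1e-9).all()
        if start + window >= gm.n_snps:
            break
        start += step
    return True


def test_duplicated_snp_column_pruned():
    rng = np.random.default_rng(4)
    calls = rng.integers(0, 3, size=(60, 10)).astype(np.int8)
    calls[:, 7] = calls[:, 2]
    gm = make_gm(calls)
    kept = au.ld_prune(gm, r2_max=0.4, window=10, step=5)
    assert ("snp2" in kept) != ("snp7" in kept) or "snp2" in kept
    assert "snp7" not in kept  # the later of the duplicate pair goes
    audit_prune(gm, kept, 0.4, 10, 5)


def test_independent_snps_survive():
    coh = synthdata.sim_admixed_genotypes([500], 300, 1, 0.1, [1.0], seed=6)
    gm = coh.genotypes
    kept = au.ld_prune(gm, r2_max=0.4, window=50, step=10)
    assert len(kept) == gm.n_snps  # independent SNPs at n=500: r2 << 0.4


def test_prune_audit_with_missing_data():
    coh = synthdata.sim_admixed_genotypes([80], 120, 1, 0.1, [1.0], seed=7,
                                          missing_rate=0.1)
    gm = coh.genotypes
    kept = au.ld_prune(gm, r2_max=0.3, window=40, step=10)
    audit_prune(gm, kept, 0.3, 40, 10)


# ---------------------------------------------------------------------------
# Weir-Cockerham F_ST
# ---------------------------------------------------------------------------

def wc_oracle_single_snp(gts1, gts2):
    """Independent scalar transcription of the two-population W&C
    variance components for one SNP (no vectorisation shared with the
    implementation)."""
    def stats(gts):
        gts = [g for g in gts if g >= 0]
        n = len(gts)
        p = sum(gts) / (2 * n)
        het = sum(1 for g in gts if g == 1) / n
        return n, p, het

    n1, p1, h1 = stats(gts1)
    n2, p2, h2 = stats(gts2)
    r = 2
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
                       / (nbar - 1))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                               - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return a, b, c


def test_wc_single_snp_matches_hand_oracle():
    # p1 = 0.2 with n1 = 10 (4 het), p2 = 0.8 with n2 = 10 (4 het)
    g1 = [1, 1, 1, 1] + [0] * 6
    g2 = [1, 1, 1, 1] + [2] * 6
    a, b, c = wc_oracle_single_snp(g1, g2)
    est = au.wc_fst_pair(np.array([g1]).T.reshape(-1, 1),
                         np.array([g2]).T.reshape(-1, 1))
    assert est == pytest.approx(a / (a + b + c), rel=1e-12)
    av, bv, cv, valid = au.wc_components_pair(
        np.array(g1).reshape(-1, 1), np.array(g2).reshape(-1, 1))
    assert av[0] == pytest.approx(a)
    assert bv[0] == pytest.approx(b)
    assert cv[0] == pytest.approx(c)


def test_wc_fixed_difference_is_one():
    g1 = np.zeros((20, 50), dtype=np.int8)
    g2 = np.full((20, 50), 2, dtype=np.int8)
    assert au.wc_fst_pair(g1, g2) == pytest.approx(1.0)


def test_wc_null_is_near_zero():
    rng = np.random.default_rng(8)
    ests = []
    for seed in range(5):
        coh = synthdata.sim_admixed_genotypes([100], 2000, 1, 0.1, [1.0],
                                              seed=seed)
        g = coh.genotypes.calls
        ests.append(au.wc_fst_pair(g[:50], g[50:]))
    assert abs(np.mean(ests)) < 0.01


def test_wc_fst_excludes_small_populations():
    coh = synthdata.sim_admixed_genotypes([10, 10, 2], 500, 3, 0.1,
                                          [8.0, 0.1, 0.1], seed=9)
    m = au.wc_fst(coh.genotypes, min_pop_n=4)
    assert m.labels == ["POP1", "POP2"]
    with pytest.raises(InvalidArgument):
        au.wc_fst(coh.genotypes, min_pop_n=11)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def test_pca_eigenvalues_match_dense_oracle(two_pop_cohort):
    gm = two_pop_cohort.genotypes.subset(snp_idx=np.arange(800))
    coords, eigvals = au.pca(gm, 5)
    # independent oracle: explicit normalised matrix + numpy eigh
    g = gm.calls.astype(float)
    n = gm.n_samples
    p_hat = (1 + g.sum(0)) / (2 + 2 * n)
    x = (g - g.mean(0)) / np.sqrt(p_hat * (1 - p_hat))
    ref = np.sort(np.linalg.eigvalsh(x @ x.T / x.shape[1]))[::-1][:5]
    assert np.allclose(eigvals, ref, atol=1e-8)


def test_pca_coordinates_centred(two_pop_cohort):
    coords, _ = au.pca(two_pop_cohort.genotypes.subset(snp_idx=np.arange(500)), 3)
    assert np.abs(coords.mean(axis=0)).max() < 1e-8


def test_pca_sign_convention(two_pop_cohort):
    coords, _ = au.pca(two_pop_cohort.genotypes.subset(snp_idx=np.arange(500)), 3)
    for k in range(coords.shape[1]):
        assert coords[np.argmax(np.abs(coords[:, k])), k] > 0


def test_pca_truncates_beyond_rank():
    gm = make_gm(np.array([[0, 1, 2], [2, 1, 0], [1, 1, 1], [0, 2, 1]]))
    coords, eigvals = au.pca(gm, 10)
    assert coords.shape[1] <= 4


# ---------------------------------------------------------------------------
# Admixture EM
# ---------------------------------------------------------------------------

def test_k1_closed_form(two_pop_cohort):
    gm = au.qc_filter(two_pop_cohort.genotypes.subset(snp_idx=np.arange(1000)),
                      maf_min=0.01)
    fit = au.admixture_em(gm, 1, seed=0)
    g = gm.calls.astype(float)
    p = g.mean(0) / 2
    ll_closed = float((g * np.log(p) + (2 - g) * np.log(1 - p)).sum())
    assert (fit.Q == 1.0).all()
    assert np.abs(fit.F[0] - p).max() < 1e-9
    assert fit.loglik == pytest.approx(ll_closed, abs=1e-6)


def test_ll_trace_monotone(admixed_cohort_k2):
    gm = admixed_cohort_k2.genotypes.subset(snp_idx=np.arange(800))
    fit = au.admixture_em(gm, 2, seed=3, max_iter=200)
    diffs = np.diff(fit.ll_trace)
    assert (diffs >= -1e-8).all()


def test_ll_invariant_to_ancestral_label_permutation(admixed_cohort_k2):
    gm = admixed_cohort_k2.genotypes.subset(snp_idx=np.arange(400))
    fit = au.admixture_em(gm, 2, seed=3, max_iter=50)
    G = gm.calls.astype(float)
    called = gm.calls != MISSING
    ll = au._admixture_loglik(G, called, fit.Q, fit.F)
    ll_perm = au._admixture_loglik(G, called, fit.Q[:, ::-1], fit.F[::-1])
    assert ll == pytest.approx(ll_perm, abs=1e-9)


def test_k_larger_than_n_errors():
    gm = make_gm(np.zeros((3, 5)))
    with pytest.raises(InvalidArgument):
        au.admixture_em(gm, 4)


def test_cv_reproducible_under_seed(admixed_cohort_k2):
    gm = admixed_cohort_k2.genotypes.subset(snp_idx=np.arange(600))
    a = au.cv_index(gm, 2, seed=11, max_iter=60)
    b = au.cv_index(gm, 2, seed=11, max_iter=60)
    assert a == b


def test_multirun_summary_arithmetic():
    def fake(ll):
        return au.AdmixtureFit(K=2, Q=np.ones((1, 2)), F=np.ones((2, 1)) / 2,
                               loglik=ll, seed=0, n_iter=1)

    same = au.multirun_summary([fake(-5.0)] * 4)
    assert same.ll_spread == 0.0 and same.converged
    mixed = au.multirun_summary([fake(-100.0), fake(-100.5), fake(-300.0)],
                                top_fraction=0.67)
    assert mixed.ll_spread == pytest.approx(0.5)
    assert mixed.converged
    with pytest.raises(InvalidArgument):
        au.multirun_summary([fake(-1.0),
                             au.AdmixtureFit(K=3, Q=np.ones((1, 3)),
                                             F=np.ones((3, 1)) / 2,
                                             loglik=-1, seed=0, n_iter=1)])
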