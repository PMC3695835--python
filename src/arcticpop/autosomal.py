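"""Autosomal SNP analyses: QC, kinship, LD pruning, F_ST, PCA, admixture.

The stages mirror a standard genome-wide population-structure workflow:
SNP filtering (autosomes, MAF, call rate), removal of close relatives with
a structure-robust kinship estimator, LD pruning by sliding-window r^2,
Weir-Cockerham pairwise F_ST, PCA with allele-frequency normalisation, and
a structure-like admixture maximum-likelihood model fitted by EM with
cross-validation over K and multi-run convergence summaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import (
    AdmixtureFit,
    FstMatrix,
    GenotypeMatrix,
    InvalidArgument,
    MISSING,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# QC filtering
# ---------------------------------------------------------------------------

@dataclass
class QcReport:
    n_input: int
    n_kept: int
    n_removed_autosome: int
    n_removed_maf: int
    n_removed_call_rate: int


def qc_filter(gm: GenotypeMatrix, maf_min: float = 0.01,
              call_rate_min: float = 0.97, autosomes_only: bool = True,
              return_report: bool = False):
    """Keep SNPs with MAF > ``maf_min`` (strict) and call rate >
    ``call_rate_min`` (strict), on chromosomes 1-22 if ``autosomes_only``."""
    auto_ok = ((gm.chromosomes >= 1) & (gm.chromosomes <= 22)) \
        if autosomes_only else np.ones(gm.n_snps, bool)
    with np.errstate(invalid="ignore"):
        maf = gm.minor_allele_freq()
    maf_ok = np.nan_to_num(maf, nan=0.0) > maf_min
    cr_ok = gm.call_rate() > call_rate_min

    keep = auto_ok & maf_ok & cr_ok
    report = QcReport(
        n_input=gm.n_snps,
        n_kept=int(keep.sum()),
        n_removed_autosome=int((~auto_ok).sum()),
        n_removed_maf=int((auto_ok & ~maf_ok).sum()),
        n_removed_call_rate=int((auto_ok & maf_ok & ~cr_ok).sum()),
    )
    logger.info("QC: kept %d/%d SNPs (removed: %d non-autosomal, %d MAF, "
                "%d call-rate)", report.n_kept, report.n_input,
                report.n_removed_autosome, report.n_removed_maf,
                report.n_removed_call_rate)
    if report.n_kept == 0:
        logger.warning("QC removed every SNP")
    out = gm.subset(snp_idx=np.where(keep)[0])
    return (out, report) if return_report else out


# ---------------------------------------------------------------------------
# Kinship (structure-robust estimator) and relative removal
# ---------------------------------------------------------------------------

def kinship_matrix(gm: GenotypeMatrix) -> np.ndarray:
    """Pairwise robust kinship phi for all sample pairs.

    phi_ij = (N_het,het - 2 * N_opposite-homozygote) / (N_het(i) + N_het(j)),
    counting over SNPs called in both samples. Diagonal is set to 0.5.
    """
    G = gm.calls
    het = (G == 1).astype(np.float64)
    hom0 = (G == 0).astype(np.float64)
    hom2 = (G == 2).astype(np.float64)
    called = (G != MISSING).astype(np.float64)

    n_hethet = het @ het.T
    n_opp = hom0 @ hom2.T + hom2 @ hom0.T
    n_het_i = het @ called.T          # het in i among jointly called
    n_het_j = called @ het.T          # het in j among jointly called
    denom = n_het_i + n_het_j
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = (n_hethet - 2.0 * n_opp) / denom
    np.fill_diagonal(phi, 0.5)
    return phi


def robust_kinship(gm: GenotypeMatrix, i: int, j: int) -> float:
    """Robust kinship between samples ``i`` and ``j``."""
    gi, gj = gm.calls[i], gm.calls[j]
    both = (gi != MISSING) & (gj != MISSING)
    if not both.any():
        raise InvalidArgument("no jointly called SNPs: kinship undefined")
    gi, gj = gi[both], gj[both]
    n_hethet = int(((gi == 1) & (gj == 1)).sum())
    n_opp = int((((gi == 0) & (gj == 2)) | ((gi == 2) & (gj == 0))).sum())
    n_het_i = int((gi == 1).sum())
    n_het_j = int((gj == 1).sum())
    denom = n_het_i + n_het_j
    if denom == 0:
        raise InvalidArgument("no heterozygous calls: kinship undefined")
    return (n_hethet - 2.0 * n_opp) / denom


# kinship above this is 2nd-degree or closer under the standard cutoffs
SECOND_DEGREE_THRESHOLD = 0.0884


def remove_relatives(gm: GenotypeMatrix,
                     threshold: float = SECOND_DEGREE_THRESHOLD,
                     return_removed: bool = False):
    """Greedily drop samples until no pair's kinship exceeds ``threshold``.

    At each step the sample involved in the most above-threshold pairs is
    removed (ties: more missingness, then sample-id order).
    """
    phi = kinship_matrix(gm)
    np.fill_diagonal(phi, 0.0)
    over = phi > threshold
    missingness = (~gm.called_mask()).sum(axis=1)
    active = np.ones(gm.n_samples, bool)
    removed: list[str] = []
    while True:
        counts = (over & active[None, :] & active[:, None]).sum(axis=1)
        counts[~active] = 0
        if counts.max(initial=0) == 0:
            break
        worst = max(
            np.where(counts == counts.max())[0],
            key=lambda i: (missingness[i], gm.sample_ids[i]),
        )
        active[worst] = False
        removed.append(gm.sample_ids[worst])
    out = gm.subset(sample_idx=np.where(active)[0])
    logger.info("relatedness filter: removed %d of %d samples",
                len(removed), gm.n_samples)
    return (out, removed) if return_removed else out


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------

def _pairwise_r2(block: np.ndarray) -> np.ndarray:
    """Pairwise-complete squared Pearson correlation between SNP columns."""
    m = block.shape[1]
    x = block.astype(float)
    x[block == MISSING] = np.nan
    valid = ~np.isnan(x)
    xz = np.nan_to_num(x)
    n = valid.T.astype(float) @ valid.astype(float)
    s = xz.T @ valid.astype(float)          # per-pair sums of x over joint calls
    ss = (xz ** 2).T @ valid.astype(float)  # per-pair sums of squares
    sxy = xz.T @ xz
    with np.errstate(divide="ignore", invalid="ignore"):
        mean_x = s / n
        mean_y = mean_x.T
        cov = sxy / n - mean_x * mean_y
        var_x = ss / n - mean_x ** 2
        var_y = var_x.T
        r2 = cov ** 2 / (var_x * var_y)
    r2[~np.isfinite(r2)] = 0.0
    np.fill_diagonal(r2, 1.0)
    return r2


def ld_prune(gm: GenotypeMatrix, r2_max: float = 0.4, window: int = 200,
             step: int = 25) -> list[str]:
    """Sliding-window LD pruning; returns kept SNP ids.

    Within each window of ``window`` SNPs (slid by ``step``), for every pair
    of retained SNPs with genotypic r^2 > ``r2_max`` the later SNP
    (chromosome/position order) is dropped. Missing genotypes are handled
    pairwise-complete.
    """
    order = np.lexsort((gm.positions, gm.chromosomes))
    calls = gm.calls[:, order]
    L = len(order)
    keep = np.ones(L, bool)
    start = 0
    while start < L:
        idx = np.arange(start, min(start + window, L))
        idx = idx[keep[idx]]
        if len(idx) > 1:
            r2 = _pairwise_r2(calls[:, idx])
            for a in range(len(idx)):
                if not keep[idx[a]]:
                    continue
                for b in range(a + 1, len(idx)):
                    if keep[idx[b]] and r2[a, b] > r2_max:
                        keep[idx[b]] = False
        if start + window >= L:
            break
        start += step
    kept_sorted = [gm.snp_ids[order[i]] for i in range(L) if keep[i]]
    logger.info("LD pruning: kept %d/%d SNPs", len(kept_sorted), L)
    return kept_sorted


# ---------------------------------------------------------------------------
# Weir-Cockerham F_ST
# ---------------------------------------------------------------------------

def wc_components_pair(g1: np.ndarray, g2: np.ndarray):
    """Per-SNP Weir-Cockerham variance components (a, b, c) for two
    populations of diploid genotypes (rows = samples, -1 = missing)."""
    r = 2.0
    comps = []
    for g in (g1, g2):
        gg = g.astype(float)
        gg[g == MISSING] = np.nan
        n_i = np.sum(~np.isnan(gg), axis=0).astype(float)
        with np.errstate(invalid="ignore"):
            p_i = np.nansum(gg, axis=0) / (2.0 * n_i)
            h_i = np.nansum(gg == 1, axis=0) / n_i
        comps.append((n_i, p_i, h_i))
    (n1, p1, h1), (n2, p2, h2) = comps

    n_bar = (n1 + n2) / r
    with np.errstate(divide="ignore", invalid="ignore"):
        n_c = (r * n_bar - (n1 ** 2 + n2 ** 2) / (r * n_bar)) / (r - 1.0)
        p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
        s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1.0) * n_bar)
        h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)

        a = (n_bar / n_c) * (
            s2 - (p_bar * (1 - p_bar) - ((r - 1) / r) * s2 - h_bar / 4.0)
            / (n_bar - 1.0))
        b = (n_bar / (n_bar - 1.0)) * (
            p_bar * (1 - p_bar) - ((r - 1) / r) * s2
            - ((2 * n_bar - 1) / (4 * n_bar)) * h_bar)
        c = h_bar / 2.0
    valid = np.isfinite(a) & np.isfinite(b) & np.isfinite(c)
    return a, b, c, valid


def wc_fst_pair(g1: np.ndarray, g2: np.ndarray) -> float:
    """Multi-locus pairwise Weir-Cockerham estimate, ratio of sums."""
    a, b, c, valid = wc_components_pair(g1, g2)
    num = np.sum(a[valid])
    den = np.sum((a + b + c)[valid])
    if den == 0:
        return 0.0
    return float(num / den)


def wc_fst(gm: GenotypeMatrix, pop_labels: Optional[Sequence[str]] = None,
           min_pop_n: int = 4) -> FstMatrix:
    """Pairwise Weir-Cockerham F_ST between populations with N >=
    ``min_pop_n``; estimates may be slightly negative and are reported as
    computed."""
    pops = list(pop_labels) if pop_labels is not None else gm.populations
    if len(pops) != gm.n_samples:
        raise InvalidArgument("pop_labels length != number of samples")
    uniq = sorted(set(pops))
    sizes = {u: sum(1 for p in pops if p == u) for u in uniq}
    eligible = [u for u in uniq if sizes[u] >= min_pop_n]
    if len(eligible) < 2:
        raise InvalidArgument(
            f"need >=2 populations with N >= {min_pop_n}; have {eligible}")
    idx = {u: [i for i, p in enumerate(pops) if p == u] for u in eligible}
    k = len(eligible)
    out = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            est = wc_fst_pair(gm.calls[idx[eligible[i]], :],
                              gm.calls[idx[eligible[j]], :])
            out[i, j] = out[j, i] = est
    return FstMatrix(labels=eligible, values=out)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def pca(gm: GenotypeMatrix, n_components: int = 10):
    """PCA of the genotype matrix with allele-frequency normalisation.

    Each SNP column is centred by its mean dosage (= 2 * the sample allele
    frequency) and scaled by sqrt(p_hat(1-p_hat)) with the smoothed
    estimate p_hat = (1 + sum g) / (2 + 2n); missing entries are imputed to
    the column mean. Returns ``(coordinates,
    eigenvalues)`` of the sample covariance; each component's sign is fixed
    so its largest-magnitude coordinate is positive.
    """
    g = gm.dosage_float()
    n = gm.n_samples
    n_called = np.sum(~np.isnan(g), axis=0)
    p_hat = (1.0 + np.nansum(g, axis=0)) / (2.0 + 2.0 * n_called)
    col_mean = np.nanmean(g, axis=0)
    x = (g - col_mean) / np.sqrt(p_hat * (1.0 - p_hat))
    x = np.nan_to_num(x)  # missing -> column mean (0 after centring)

    cov = x @ x.T / x.shape[1]
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]

    rank = int(np.sum(eigvals > 1e-10))
    if n_components > rank:
        logger.warning("requested %d components but rank is %d; truncating",
                       n_components, rank)
        n_components = rank
    eigvals = eigvals[:n_components]
    coords = eigvecs[:, :n_components] * np.sqrt(np.maximum(eigvals, 0) * n)
    for k in range(coords.shape[1]):
        jmax = np.argmax(np.abs(coords[:, k]))
        if coords[jmax, k] < 0:
            coords[:, k] = -coords[:, k]
    return coords, eigvals


# ---------------------------------------------------------------------------
# Structure-like admixture model, EM
# ---------------------------------------------------------------------------

EPS_F = 1e-6


def _admixture_loglik(G: np.ndarray, called: np.ndarray, Q: np.ndarray,
                      F: np.ndarray) -> float:
    P = np.clip(Q @ F, 1e-12, 1 - 1e-12)
    g = np.where(called, G, 0.0)
    ll = g * np.log(P) + (2.0 - g) * np.log1p(-P)
    return float(np.sum(ll[called]))


def admixture_em(gm: GenotypeMatrix, K: int, seed: int = 0,
                 tol: float = 1e-4, max_iter: int = 2000,
                 accelerate: bool = True) -> AdmixtureFit:
    """Fit the admixture model g_il ~ Binomial(2, sum_k q_ik f_kl) by EM.

    The log-likelihood is non-decreasing across recorded iterations;
    fitting stops when the LL improvement falls below ``tol``. Q rows are
    initialised from a flat Dirichlet, F from perturbed global allele
    frequencies. Missing genotypes are skipped term-wise.

    With ``accelerate`` (default) each recorded iteration is a SQUAREM
    extrapolation cycle built from plain EM steps, with a fallback to the
    unextrapolated step whenever extrapolation fails to improve the LL —
    so the monotonicity guarantee of EM is preserved exactly.
    """
    if K < 1:
        raise InvalidArgument("K must be >= 1")
    if K > gm.n_samples:
        raise InvalidArgument("K cannot exceed the number of samples")
    rng = np.random.default_rng(seed)
    G = gm.calls.astype(float)
    called = gm.calls != MISSING
    G[~called] = 0.0
    G2 = 2.0 - G
    G2[~called] = 0.0
    n, L = G.shape
    n_terms = 2.0 * called.sum(axis=1)  # alleles observed per individual

    Q = rng.dirichlet(np.ones(K), size=n)
    with np.errstate(invalid="ignore"):
        p_glob = np.where(called, G, np.nan)
        p_glob = np.nanmean(p_glob, axis=0) / 2.0
    p_glob = np.nan_to_num(p_glob, nan=0.5)
    F = np.clip(p_glob[None, :] + rng.normal(0, 0.05, size=(K, L)),
                EPS_F, 1 - EPS_F)

    def loglik(Q: np.ndarray, F: np.ndarray) -> float:
        P = np.clip(Q @ F, 1e-12, 1 - 1e-12)
        return float(np.sum(G * np.log(P)) + np.sum(G2 * np.log1p(-P)))

    def em_step(Q: np.ndarray, F: np.ndarray):
        # row/column sums of the expected allele-origin counts factor
        # through matrix products: no n x L x K temporaries are formed
        P = np.clip(Q @ F, 1e-12, 1 - 1e-12)
        ratio_alt = G / P
        ratio_ref = G2 / (1.0 - P)
        Q_new = (ratio_alt @ F.T + ratio_ref @ (1.0 - F).T) * Q \
            / n_terms[:, None]
        col_a = (ratio_alt.T @ Q).T * F
        col_b = (ratio_ref.T @ Q).T * (1.0 - F)
        with np.errstate(divide="ignore", invalid="ignore"):
            F_new = col_a / (col_a + col_b)
        F_new = np.clip(np.nan_to_num(F_new, nan=0.5), EPS_F, 1 - EPS_F)
        Q_new = np.maximum(Q_new, 0.0)
        Q_new = Q_new / Q_new.sum(axis=1, keepdims=True)
        return Q_new, F_new

    def project(Q: np.ndarray, F: np.ndarray):
        Q = np.maximum(Q, 1e-9)
        return Q / Q.sum(axis=1, keepdims=True), np.clip(F, EPS_F, 1 - EPS_F)

    trace: list[float] = []
    ll = loglik(Q, F)
    for _ in range(max_iter):
        if not accelerate:
            Q, F = em_step(Q, F)
        else:
            Q1, F1 = em_step(Q, F)
            Q2, F2 = em_step(Q1, F1)
            rQ, rF = Q1 - Q, F1 - F
            vQ, vF = (Q2 - Q1) - rQ, (F2 - F1) - rF
            vnorm = np.sum(vQ ** 2) + np.sum(vF ** 2)
            if vnorm < 1e-24:
                Q, F = Q2, F2
            else:
                alpha = -np.sqrt((np.sum(rQ ** 2) + np.sum(rF ** 2)) / vnorm)
                alpha = min(alpha, -1.0)
                Qs, Fs = project(Q - 2 * alpha * rQ + alpha ** 2 * vQ,
                                 F - 2 * alpha * rF + alpha ** 2 * vF)
                Qs, Fs = em_step(Qs, Fs)  # stabilisation step
                if loglik(Qs, Fs) >= loglik(Q2, F2):
                    Q, F = Qs, Fs
                else:
                    Q, F = Q2, F2  # safeguard: plain EM, monotone
        ll_new = loglik(Q, F)
        trace.append(ll_new)
        if ll_new - ll < tol and len(trace) > 1:
            ll = ll_new
            break
        ll = ll_new
    return AdmixtureFit(K=K, Q=Q, F=F, loglik=ll, seed=seed, n_iter=len(trace),
                        ll_trace=trace)


def cv_index(gm: GenotypeMatrix, K: int, mask_fraction: float = 0.1,
             seed: int = 0, **fit_kwargs) -> float:
    """Cross-validation index for model choice over K: mask a random
    fraction of called genotype entries, refit, and score the masked
    entries by mean squared deviation between the observed dosage and the
    model's expected dosage 2 * sum_k q_ik f_kl. Lower is better."""
    if not 0 < mask_fraction < 1:
        raise InvalidArgument("mask_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    called_idx = np.argwhere(gm.calls != MISSING)
    n_mask = max(1, int(round(mask_fraction * len(called_idx))))
    chosen = called_idx[rng.choice(len(called_idx), size=n_mask, replace=False)]

    masked = gm.calls.copy()
    masked[chosen[:, 0], chosen[:, 1]] = MISSING
    gm_masked = GenotypeMatrix(
        calls=masked, sample_ids=gm.sample_ids, populations=gm.populations,
        snp_ids=gm.snp_ids, chromosomes=gm.chromosomes, positions=gm.positions,
        alleles=gm.alleles)
    fit = admixture_em(gm_masked, K, seed=seed, **fit_kwargs)
    pred = 2.0 * (fit.Q @ fit.F)
    obs = gm.calls[chosen[:, 0], chosen[:, 1]].astype(float)
    return float(np.mean((obs - pred[chosen[:, 0], chosen[:, 1]]) ** 2))


@dataclass
class MultirunSummary:
    best: AdmixtureFit
    ll_spread: float
    converged: bool
    top_lls: list[float] = field(default_factory=list)


def multirun_summary(fits: Sequence[AdmixtureFit],
                     top_fraction: float = 0.10) -> MultirunSummary:
    """Best fit and the LL spread within the top fraction of runs.

    ``converged`` flags a spread < 1 LL unit among the top
    floor(top_fraction * n_runs) runs (at least one) — evidence that
    repeated runs reach the same optimum.
    """
    if not fits:
        raise InvalidArgument("need at least one fit")
    ks = {f.K for f in fits}
    if len(ks) != 1:
        raise InvalidArgument(f"fits have mixed K: {sorted(ks)}")
    lls = sorted((f.loglik for f in fits), reverse=True)
    n_top = max(1, int(top_fraction * len(fits)))
    top = lls[:n_top]
    spread = top[0] - top[-1]
    best = max(fits, key=lambda f: f.loglik)
    return MultirunSummary(best=best, ll_spread=spread,
                           converged=spread < 1.0, top_lls=top)
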