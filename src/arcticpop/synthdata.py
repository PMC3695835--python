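"""Seeded generators for synthetic inputs with known structure.

Every downstream stage of the pipeline has a generator here that produces
data from the statistical model the stage assumes, so estimator behaviour
can be checked against known truth without any external download:

* :func:`sim_star_clade` — a star genealogy with Poisson(expected_subs)
  substitutions per lineage (the data model behind the rho statistic);
* :func:`sim_str_evolution` — single-step stepwise mutation of STR repeat
  counts from a founder (the model behind ASD dating), with a reflecting
  floor at one repeat;
* :func:`sim_admixed_genotypes` — Balding-Nichols population allele
  frequencies around a shared ancestral frequency with Dirichlet ancestry
  proportions and binomial genotypes (the model behind F_ST, PCA and the
  admixture fit);
* :func:`sim_correlated_distances` — pairs of distance matrices whose
  off-diagonal Pearson correlation is controlled exactly (for Mantel
  calibration);
* :func:`sim_mt_cohort` — an mtDNA haplotype table drawn from a marker
  tree with prescribed clade composition.

All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .core import (
    GenotypeMatrix,
    DistanceMatrix,
    InvalidArgument,
    PhyloNode,
    SimAdmixedCohort,
    SimStarClade,
    StrHaplotype,
)
from .mt_phylo import DEFAULT_POLICY, ExclusionPolicy, HaplogroupTree, MT_LENGTH

BASES = "ACGT"


# ---------------------------------------------------------------------------
# Star clades for rho
# ---------------------------------------------------------------------------

def _allowed_positions(policy: ExclusionPolicy) -> np.ndarray:
    banned = set(policy.excluded_sites)
    for lo, hi in policy.length_variant_ranges:
        banned.update(range(lo, hi + 1))
    banned.update(policy.conditional_transversions)
    banned.add(policy.conditional_trigger_site)
    return np.array([p for p in range(1, MT_LENGTH + 1) if p not in banned])


def sim_star_clade(n_tips: int, expected_subs: float, seed: int,
                   policy: ExclusionPolicy = DEFAULT_POLICY) -> SimStarClade:
    """Simulate a star-like clade expansion.

    Each of ``n_tips`` lineages carries an i.i.d. Poisson(``expected_subs``)
    number of substitutions placed infinite-sites style on positions that
    no exclusion rule touches (so simulated data passes filters intact).
    When the global site pool is too small for unique placement across the
    whole clade, uniqueness is kept within each tip only.
    """
    if n_tips < 1:
        raise InvalidArgument("n_tips must be >= 1")
    if expected_subs < 0:
        raise InvalidArgument("expected_subs must be >= 0")
    rng = np.random.default_rng(seed)
    counts = rng.poisson(expected_subs, size=n_tips)
    pool = _allowed_positions(policy)
    total = int(counts.sum())
    globally_unique = total <= len(pool)
    if globally_unique:
        sites = rng.choice(pool, size=total, replace=False)
    root = PhyloNode(name="root")
    haplotypes: list[frozenset[str]] = []
    offset = 0
    for i, k in enumerate(counts):
        k = int(k)
        if globally_unique:
            positions = sites[offset:offset + k]
            offset += k
        else:
            positions = rng.choice(pool, size=k, replace=False)
        tokens = frozenset(f"{p}{rng.choice(list(BASES))}" for p in positions)
        tip = PhyloNode(name=f"tip{i}", edge_count=k, n_samples=1)
        root.add_child(tip)
        haplotypes.append(tokens)
    return SimStarClade(n_tips=n_tips, expected_subs=expected_subs,
                        tree=root, haplotypes=haplotypes)


# ---------------------------------------------------------------------------
# Stepwise STR evolution
# ---------------------------------------------------------------------------

def sim_str_evolution(n_chrom: int, n_loci: int, generations: int,
                      mu_locus: float, founder: StrHaplotype,
                      seed: int) -> list[StrHaplotype]:
    """Evolve ``n_chrom`` chromosomes from the founder under the stepwise
    mutation model: per locus per generation, probability ``mu_locus`` of a
    +/-1 repeat change; repeat counts reflect at the floor of 1."""
    if n_loci < 1:
        raise InvalidArgument("n_loci must be >= 1")
    if not 0 <= mu_locus < 1:
        raise InvalidArgument("mu_locus must be in [0, 1)")
    if len(founder.loci) != n_loci:
        raise InvalidArgument("founder has wrong number of loci")
    rng = np.random.default_rng(seed)
    out = []
    base = np.array(founder.repeats, dtype=int)
    # one Bernoulli(mu) per generation per locus -> Binomial(t, mu) events,
    # applied sequentially so the reflecting floor at 1 is honoured
    n_events = rng.binomial(generations, mu_locus, size=(n_chrom, n_loci))
    for i in range(n_chrom):
        reps = base.copy()
        for j in range(n_loci):
            for _ in range(int(n_events[i, j])):
                step = 1 if rng.random() < 0.5 else -1
                reps[j] = reps[j] + step if reps[j] + step >= 1 else reps[j] + 1
        out.append(founder.with_repeats(reps))
    return out


# ---------------------------------------------------------------------------
# Balding-Nichols admixed cohorts
# ---------------------------------------------------------------------------

def sim_admixed_genotypes(n_per_pop: Sequence[int], n_snps: int, K: int,
                          fst_param: float, dirichlet_alpha: Sequence[float],
                          seed: int, missing_rate: float = 0.0,
                          pop_labels: Optional[Sequence[str]] = None
                          ) -> SimAdmixedCohort:
    """Simulate admixed diploid genotypes.

    Per SNP: ancestral frequency p ~ Uniform(0.05, 0.95); each of K
    ancestral populations draws its frequency from
    Beta(p(1-F)/F, (1-p)(1-F)/F) (Balding-Nichols with differentiation F).
    Individuals in sampling group g draw ancestry proportions
    Q ~ Dirichlet(alpha rotated so component g dominates when alpha is
    one-hot-like), and genotypes ~ Binomial(2, sum_k q_ik f_kl). A
    ``missing_rate`` > 0 masks entries at random so QC paths are testable.
    """
    if not 0 < fst_param < 1:
        raise InvalidArgument("fst_param must be in (0, 1)")
    if K < 1:
        raise InvalidArgument("K must be >= 1")
    alpha = np.asarray(dirichlet_alpha, dtype=float)
    if alpha.shape != (K,):
        raise InvalidArgument(f"dirichlet_alpha must have length K={K}")
    if not 0 <= missing_rate < 1:
        raise InvalidArgument("missing_rate must be in [0, 1)")
    n_per_pop = list(n_per_pop)
    n_groups = len(n_per_pop)
    rng = np.random.default_rng(seed)

    p_anc = rng.uniform(0.05, 0.95, size=n_snps)
    F = fst_param
    a = p_anc * (1 - F) / F
    b = (1 - p_anc) * (1 - F) / F
    F_true = np.clip(rng.beta(a, b, size=(K, n_snps)), 1e-6, 1 - 1e-6)

    rows_Q, pops = [], []
    labels = (list(pop_labels) if pop_labels is not None
              else [f"POP{g + 1}" for g in range(n_groups)])
    for g, n_g in enumerate(n_per_pop):
        # rotate alpha so group g maps to ancestral component g (mod K):
        # one-hot-like alphas then give each sampling group its own ancestry
        alpha_g = np.roll(alpha, g % K)
        rows_Q.append(rng.dirichlet(alpha_g, size=n_g))
        pops.extend([labels[g]] * n_g)
    Q_true = np.vstack(rows_Q)
    n = Q_true.shape[0]

    P = Q_true @ F_true
    calls = rng.binomial(2, P).astype(np.int8)
    if missing_rate > 0:
        mask = rng.random(calls.shape) < missing_rate
        calls[mask] = -1

    gm = GenotypeMatrix(
        calls=calls,
        sample_ids=[f"S{i + 1}" for i in range(n)],
        populations=pops,
        snp_ids=[f"snp{j + 1}" for j in range(n_snps)],
        chromosomes=np.repeat(np.arange(1, 23), int(np.ceil(n_snps / 22)))[:n_snps],
        positions=np.arange(1, n_snps + 1) * 1000,
        alleles=[("A", "C")] * n_snps,
    )
    return SimAdmixedCohort(Q_true=Q_true, F_true=F_true, genotypes=gm,
                            fst_param=fst_param, dirichlet_alpha=alpha)


# ---------------------------------------------------------------------------
# Correlated distance matrices
# ---------------------------------------------------------------------------

def sim_correlated_distances(n_items: int, target_r: float,
                             seed: int) -> tuple[DistanceMatrix, DistanceMatrix]:
    """Two distance matrices whose off-diagonal entries have Pearson
    correlation ``target_r`` in expectation (sampling noise ~ m^-1/2 with
    m = n(n-1)/2 entries, i.e. within about +/-0.05 for n >= 30), shifted
    to be non-negative.

    The construction is deliberately stochastic — the second matrix mixes
    an independent component rather than being orthogonalised to hit the
    target exactly — so that at ``target_r = 0`` the pair is a genuine
    null draw and permutation p-values are uniform.
    """
    if n_items < 3:
        raise InvalidArgument("n_items must be >= 3")
    if abs(target_r) > 1:
        raise InvalidArgument("|target_r| must be <= 1")
    rng = np.random.default_rng(seed)
    m = n_items * (n_items - 1) // 2
    z1 = rng.standard_normal(m)
    z2 = rng.standard_normal(m)
    z1 = (z1 - z1.mean()) / z1.std()
    z2 = (z2 - z2.mean()) / z2.std()
    y = target_r * z1 + np.sqrt(1 - target_r ** 2) * z2

    def to_matrix(v: np.ndarray) -> np.ndarray:
        v = v - v.min() + 0.1  # positive entries; affine shift keeps r
        out = np.zeros((n_items, n_items))
        iu = np.triu_indices(n_items, k=1)
        out[iu] = v
        return out + out.T

    labels = [f"P{i + 1}" for i in range(n_items)]
    return (DistanceMatrix(labels, to_matrix(z1)),
            DistanceMatrix(labels, to_matrix(y)))


# ---------------------------------------------------------------------------
# mtDNA cohorts from a marker tree
# ---------------------------------------------------------------------------

def sim_mt_cohort(tree: HaplogroupTree,
                  composition: dict[str, dict[str, float]],
                  n_per_pop: dict[str, int], seed: int,
                  private_variant_rate: float = 0.6,
                  policy: ExclusionPolicy = DEFAULT_POLICY):
    """Draw an mtDNA haplotype table from a marker tree.

    ``composition`` maps population -> {haplogroup: probability}; each
    sample takes the cumulative defining variants of its drawn haplogroup
    plus Poisson(``private_variant_rate``) private HVSI variants at
    non-excluded positions. Returns a
    :class:`~arcticpop.formats_io.MtHaplotypeTable`.
    """
    from .formats_io import MtHaplotypeTable, MtRecord
    from .mt_phylo import parse_variant_list

    rng = np.random.default_rng(seed)
    hvsi_pool = [p for p in _allowed_positions(policy)
                 if 16017 <= p <= 16399]
    records = []
    idx = 0
    for pop, n in n_per_pop.items():
        probs = composition[pop]
        groups = sorted(probs)
        pvec = np.array([probs[g] for g in groups], dtype=float)
        pvec = pvec / pvec.sum()
        draws = rng.choice(len(groups), size=n, p=pvec)
        for d in draws:
            idx += 1
            node = tree.node(groups[d])
            tokens: list[str] = []
            for nd in node.path_from_root()[1:]:
                tokens.extend(nd.edge_variants)
            n_priv = rng.poisson(private_variant_rate)
            if n_priv:
                taken = {int(t[:-1]) for t in tokens
                         if t[:-1].isdigit()}
                avail = [p for p in hvsi_pool if p not in taken]
                priv = rng.choice(avail, size=min(n_priv, len(avail)),
                                  replace=False)
                tokens.extend(f"{p}{rng.choice(list('ACGT'))}" for p in priv)
            text = " ".join(tokens)
            records.append(MtRecord(
                sample_id=f"{pop}{idx}", population=pop,
                variants=parse_variant_list(text), raw_variants=text))
    return MtHaplotypeTable(records)
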