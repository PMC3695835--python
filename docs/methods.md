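# Methods

This note documents the models, estimators, numerical choices and known
limitations of the package, and states what the synthetic-data
generators do and do not emulate.

## mtDNA variants and site exclusion

Variants are notated against the mtDNA reference (1-based positions on
the 16,569-bp circle, matching the rCRS/RSRS convention). The parser
accepts anchored (`A11252G`) and unanchored (`16189C`) substitutions —
capital letters are transitions, lowercase transversions — reversals
(`!` suffix), insertions (`315.1C`), deletions (`16166d`), and IUPAC
ambiguity codes for heteroplasmies. Heteroplasmic positions are treated
as missing for classification and excluded from substitution counts.

The default exclusion policy removes the hypervariable site 16519,
insertions/deletions in the poly-C stretches 303–315 and 16184–16194,
and A–C transversions at 16182/16183 whenever the 16189 C transition is
present in the same haplotype (they arise as artefacts of that
transition). Substitutions inside the poly-C ranges are kept; only
length variation is excluded.

## Haplogroup classification

The marker tree is data, not code: a YAML config of
`node: {parent, variants}`, with one bundled synthetic mtDNA tree and
one synthetic Y biallelic tree (file names and headers mark them as
synthetic stand-ins; the handful of defining variants that are well
established for the terminal clades of interest are real, the rest are
placeholders). Classification walks every node, accumulating the
expected derived state along the root path; a `!`-suffixed edge token
removes the base token from the expected state and adds it to a
required-absent set.

Candidates are ranked by the number of satisfied marker requirements
(present + required-absent), which equals path depth in variants for
ordinary nested clades. Raw node depth is deliberately not the key: a
clade defined by a reversal has a weaker net present-requirement than
its siblings and would otherwise capture sibling samples it does not
explain. Ties break by fewest unexplained private variants, then name
order. One consequence: a sample whose observed state is identical to
both an ancestor and its reversal-defined descendant (e.g. C5a vs
C5a2a, which differ only in history, not state) is assigned to the
descendant, since the reversal counts as a confirmed marker;
single-segment data cannot distinguish the two.

## Haplotype spectra

Haplotype identity is post-filter variant-set equality, in two modes:
the full variant set, or HVSI-range (np 16017–16399) variants only —
both counts are reported because published totals do not always state
which definition they use. Population pooling (e.g. merging two
sampling series of the same ethnic group) is an explicit label map.

## Rho dating

For a clade with n sampled tips, ρ is the mean number of substitutions
on root-to-tip paths and σ² = Σₑ (nₑ/n)²·lₑ over edges (nₑ tips below
edge e, lₑ substitutions on it) — the genealogy-aware standard error of
the founder-age estimator. Conversion to years is a deliberate linear
clock, t = ρ/(μL) with defaults μ = 1.665×10⁻⁸ substitutions/site/year
and L = 16,569; the 95% CI is (ρ ± 1.96σ)/(μL) clipped at zero.
Published analyses sometimes use a nonlinear substitution-to-years
transform that corrects for purifying selection on recent
non-synonymous variation; that correction is out of scope here, so ages
of very young clades will be slightly underestimated relative to such
calculators. Intra-clade trees for dating are rebuilt from haplotype
variant sets by greedy perfect-phylogeny grouping (most frequent shared
variant first; a variant needing several placements is flagged as
recurrent; ties break lexicographically for determinism).

## Median-joining networks

STR distance is weighted L1 on repeat counts (one step per repeat
unit, the standard convention for Y-STR networks), uniform weights by
default. The construction iterates: (i) the ε-relaxed minimum spanning
network over current nodes (a pair is linked iff its distance is within
ε of the minimax-path weight between them; ε = 0 gives the union of all
MSTs); (ii) coordinate-wise medians of node triples are proposed, and
the proposal that most reduces the minimum spanning length is accepted
(strict decrease required — this is what makes median nodes "Steiner
points"); (iii) medians whose removal no longer lengthens the network
are pruned. The result is deterministic given the input (ties on
candidate medians break by tuple order). On instances small enough for
exhaustive search, the final length matches a brute-force Steiner
search over the lattice bounding box; in general it lies between the
Steiner minimum and the MST length. The implementation enumerates all
node triples per round, which is O(n³·n² log n) per iteration — fine
for the tens-to-low-hundreds of distinct haplotypes typical of
single-haplogroup STR networks, not for thousands.

## ASD dating

ASD is the mean over loci of the carrier-weighted mean squared repeat
difference from the founder haplotype. Under the single-step stepwise
mutation model E[ASD] = μt, so t = ASD/μ generations; defaults
μ = 6.9×10⁻⁴ per locus per generation and 25-year generations, both
exposed as parameters since rate conventions differ between
applications. The founder is configurable; the default is the
carrier-frequency-weighted per-locus modal haplotype (ties to the
smaller repeat). ASD is unbiased for t only while lineages evolve
freely; the reflecting floor at one repeat (needed for a well-defined
simulation) biases it downward in the extreme-low-repeat regime, which
real Y-STR alleles (10–30 repeats) never reach.

## Autosomal estimators

*QC.* Strict inequalities, per the usual phrasing "MAF > 1%,
genotyping success > 97%": a SNP at exactly the threshold is removed.
Non-autosomal SNPs are dropped first; removal counts are reported per
criterion so that input = kept + removed at every stage.

*Kinship.* The structure-robust estimator
φ = (N_het,het − 2·N_opposite-hom)/(N_het(i)+N_het(j)) over jointly
called SNPs: 0.5 for duplicates/MZ twins, ≈0.25 for parent–offspring,
≈0 for unrelated pairs, without needing population allele frequencies.
Relative removal is greedy — repeatedly drop the sample with the most
above-threshold partners (ties: more missingness, then id order) —
with the 2nd-degree cutoff 0.0884 (the midpoint convention
2^(−7/2)...2^(−5/2) places 2nd-degree pairs above it).

*LD pruning.* Within each 200-SNP window (stepped by 25), the later SNP
of any retained pair with pairwise-complete dosage r² > 0.4 is dropped;
the audit (no violating pair in any window of the output) is part of
the test suite.

*F_ST.* Weir–Cockerham variance components a (among-population), b, c
per SNP for each population pair, combined as Σa/Σ(a+b+c) across SNPs
(ratio of sums, the standard multi-locus form — not the mean of
per-SNP ratios, which is biased for rare variants). Estimates can be
slightly negative and are reported as computed; only the Slatkin
linearization step clips negatives (with a log message). Populations
below the minimum sample size (default 4) are excluded.

*PCA.* SNP columns are centred by their mean dosage and scaled by
sqrt(p̂(1−p̂)) with the smoothed estimate p̂ = (1+Σg)/(2+2n); missing
entries impute to the column mean (zero after centring); the n×n sample
covariance is eigendecomposed. Exact column centring makes coordinate
means zero to machine precision. Signs follow the convention that each
component's largest-magnitude coordinate is positive.

*Admixture.* The likelihood is the binomial mixture
g_il ~ Bin(2, Σₖ q_ik f_kl), maximised by EM on (Q, F) with missing
genotypes skipped term-wise. F is clipped to [10⁻⁶, 1−10⁻⁶] (so K = 1
reproduces observed frequencies exactly up to that clip on monomorphic
SNPs). Each recorded iteration is a SQUAREM extrapolation cycle built
from plain EM steps with a fallback to the unextrapolated step whenever
extrapolation fails to improve the likelihood, so the recorded LL trace
is non-decreasing exactly as for plain EM, at roughly an order of
magnitude fewer iterations. Initialisation: Q from a flat Dirichlet, F
from globally estimated frequencies plus Gaussian noise (σ = 0.05),
both seeded; multi-start with different seeds substitutes for more
elaborate optimisation, and `multirun_summary` reports the LL spread
within the top fraction of runs (converged when < 1 LL unit).
Cross-validation masks a random fraction (default 10%) of called
entries, refits, and scores masked entries by squared deviation between
observed dosage and 2·Σₖ q̂f̂ — entry masking rather than fold
partitioning, since the model factorises over entries.

## Distance matrices and Mantel tests

Geographic distances are haversine great circles (Earth radius
6371 km). Linguistic distances use the ordinal scheme 0 (same
language), 1 (same branch of a family), 2 (different branches of the
same family), 3 (different families), with branches meaning the major
subfamilies nearest the family root. The Mantel statistic is the
Pearson correlation of off-diagonal upper-triangle entries;
significance comes from jointly permuting the row/column labels of the
second matrix, one-sided for positive association (matching the
directional claims such tests are used for). The Monte-Carlo p-value
uses the add-one estimator (1+c)/(B+1), so p is never zero and
"p < 0.001 at 100,000 permutations" is representable; for n ≤ 7 all n!
permutations are enumerated and p is exact. The partial statistic is
the first-order partial correlation
r_xy·z = (r_xy − r_xz·r_yz)/√((1−r_xz²)(1−r_yz²)), with Y-label
permutation of the partial statistic itself; a constant control matrix
collapses it to the simple test, and |r_xz| = 1 or |r_yz| = 1 is
rejected as degenerate. The library default is 100,000 permutations;
the analysis scripts use 10,000 and the test suite hundreds-to-
thousands, which bounds the p-value resolution accordingly.

## Synthetic data: what it emulates, what it does not

* `sim_star_clade` — a star genealogy with i.i.d. Poisson(m)
  substitutions per lineage, placed infinite-sites style on positions
  untouched by the exclusion policy (falling back to within-tip
  uniqueness if the site pool is exhausted). This is exactly the data
  model under which ρ is unbiased with the stated σ; it does not model
  non-star genealogies, rate heterogeneity across sites, or recurrent
  mutation, so tests passing on it validate the estimator, not the
  clock or tree shape assumptions on real data.
* `sim_str_evolution` — per locus per generation, a repeat changes ±1
  with probability μ (Binomial event counts applied as sequential
  reflected steps; the floor at one repeat is the only boundary).
  Single-step SMM only: no multi-step mutations, no rate variation
  across loci.
* `sim_admixed_genotypes` — ancestral frequency p ~ U(0.05, 0.95) per
  SNP; population frequencies Beta(p(1−F)/F, (1−p)(1−F)/F)
  (Balding–Nichols, so the simulated differentiation parameter equals
  the expected Wright F_ST); ancestry rows Dirichlet(α), rotated per
  sampling group so one-hot-like α gives each group its own dominant
  component; genotypes Binomial(2, QF); optional uniform missingness.
  SNPs are independent given frequencies — there is deliberately no LD,
  so LD pruning is validated on its definitional audit rather than on
  realistic haplotype structure.
* `sim_correlated_distances` — two symmetric zero-diagonal matrices
  whose off-diagonal entries correlate at the target in expectation
  (sampling noise ~ m^{-1/2}, within about ±0.05 at n ≥ 30). The
  construction is deliberately stochastic rather than exactly
  normalised: an exactly-attained r = 0 would pin the observed Mantel
  statistic at its permutation-distribution median and make type-I
  calibration meaningless. Entries are i.i.d., not metric distances; the
  Mantel test does not require the triangle inequality.
* `sim_mt_cohort` — samples haplogroups per population from prescribed
  probabilities, takes each clade's cumulative defining variants, and
  adds Poisson(0.6) private HVSI variants at non-excluded positions
  (0.6 private control-region variants per lineage is a realistic
  within-clade diversity for young expansions). Composition defaults in
  the analysis scripts mirror a five-population Northeast-Siberian
  survey: C- and D-dominated East Asian ancestry (~43% and ~30%), ~8%
  West Eurasian, ~2% Northeast-Siberian-specific lineages, n = 829.

All generators take an integer seed and are bit-reproducible.

## Problem sizes

Desk-scale defaults were chosen so each estimator's validation runs in
seconds to a couple of minutes on one core: 5,000 SNPs × 100 samples
for F_ST/PCA/admixture recovery, 200-tip star clades × 100 seeds for ρ,
500 chromosomes × 6 loci for ASD, 200 replicates × 199 permutations for
Mantel calibration, and ≤ 4-haplotype lattices for the exhaustive
Steiner cross-check. The pipeline itself has no size assumptions beyond
memory; the study-scale parameter defaults (100 EM runs at K = 2..14,
100,000 permutations) remain the config defaults.

## Known limitations

* The bundled marker trees are synthetic stand-ins; real analyses
  should supply a curated tree config.
* The linear molecular clock omits selection correction (above).
* The MJ implementation targets single-haplogroup STR networks, not
  genome-scale inputs, and implements ε only in the link-sparsification
  step (median proposals always require strict improvement, which keeps
  the node set finite).
* Admixture EM finds local optima; multi-start plus the LL-spread
  convergence flag is the mitigation, as in common practice.
* Binary PLINK (BED), VCF and IDAT inputs are out of scope; text
  PED/MAP only.
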