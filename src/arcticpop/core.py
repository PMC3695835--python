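"""Shared in-memory containers for the analysis pipeline.

The pipeline moves a small set of objects between its stages:

* :class:`Variant` / variant-token sets — parsed mtDNA (or Y biallelic)
  mutations notated against a reference sequence;
* :class:`PhyloNode` — a rooted tree whose edges carry substitution counts
  and (optionally) defining variants; used both for haplogroup marker trees
  and for reconstructed intra-clade haplotype trees;
* :class:`StrHaplotype` — a Y-STR haplotype as per-locus repeat counts with
  a carrier count;
* :class:`GenotypeMatrix` — diploid autosomal dosages {0,1,2,missing};
* :class:`DistanceMatrix` — a labelled symmetric matrix with zero diagonal.

Result records (:class:`AgeEstimate`, :class:`AdmixtureFit`,
:class:`FstMatrix`, :class:`MantelResult`) are plain dataclasses so they can
be serialised trivially.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np

MISSING = -1  # genotype missing code in GenotypeMatrix.calls

# IUPAC ambiguity codes (heteroplasmy notation); plain bases excluded
IUPAC_AMBIGUOUS = set("RYSWKMBDHVN")


class ArcticPopError(Exception):
    """Base class for errors raised by this package."""


class ParseError(ArcticPopError):
    pass


class InvalidArgument(ArcticPopError):
    pass


# ---------------------------------------------------------------------------
# Variants
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Variant:
    """A single mtDNA mutation notated against the reference.

    ``kind`` is one of ``transition``, ``transversion``, ``insertion``,
    ``deletion``, ``heteroplasmy``. ``back_mutation`` marks a reversal
    (token suffixed with ``!``).
    """

    position: int
    kind: str
    ref: Optional[str] = None
    alt: Optional[str] = None
    insert_index: int = 0
    back_mutation: bool = False

    @property
    def token(self) -> str:
        """Canonical token used for set comparisons."""
        bang = "!" if self.back_mutation else ""
        if self.kind == "insertion":
            return f"{self.position}.{self.insert_index}{self.alt}"
        if self.kind == "deletion":
            return f"{self.position}d{bang}"
        return f"{self.position}{self.alt}{bang}"

    @property
    def base_token(self) -> str:
        """Token without the back-mutation flag."""
        return self.token.rstrip("!")

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.token


# ---------------------------------------------------------------------------
# Rooted trees (marker trees, reconstructed haplotype trees, star clades)
# ---------------------------------------------------------------------------

@dataclass
class PhyloNode:
    """Node of a rooted tree; edge attributes describe the edge to *parent*."""

    name: str
    parent: Optional["PhyloNode"] = None
    children: list["PhyloNode"] = field(default_factory=list)
    edge_variants: tuple[str, ...] = ()  # defining variant tokens on edge above
    edge_count: int = 0                  # substitutions on edge above
    n_samples: int = 0                   # sampled haplotypes sitting at this node
    recurrent: tuple[str, ...] = ()      # variant tokens flagged as recurrent

    def add_child(self, child: "PhyloNode") -> "PhyloNode":
        child.parent = self
        self.children.append(child)
        return child

    def walk(self) -> Iterator["PhyloNode"]:
        yield self
        for c in self.children:
            yield from c.walk()

    def tips(self) -> list["PhyloNode"]:
        return [n for n in self.walk() if not n.children]

    def find(self, name: str) -> Optional["PhyloNode"]:
        for n in self.walk():
            if n.name == name:
                return n
        return None

    def path_from_root(self) -> list["PhyloNode"]:
        path = []
        node: Optional[PhyloNode] = self
        while node is not None:
            path.append(node)
            node = node.parent
        return list(reversed(path))

    def depth_count(self) -> int:
        """Total substitutions on the path from the root to this node."""
        return sum(n.edge_count for n in self.path_from_root()[1:])

    def to_newick(self) -> str:
        def fmt(node: PhyloNode) -> str:
            label = node.name.replace(" ", "_")
            if node.children:
                inner = ",".join(fmt(c) for c in node.children)
                return f"({inner}){label}:{node.edge_count}"
            return f"{label}:{node.edge_count}"

        if self.children:
            inner = ",".join(fmt(c) for c in self.children)
            return f"({inner}){self.name.replace(' ', '_')};"
        return f"{self.name};"


@dataclass
class HaplogroupTree:
    """Rooted marker tree: each edge carries the defining variant tokens.

    Works identically for the mtDNA haplogroup hierarchy and for Y
    biallelic marker trees (where tokens are marker names such as ``M217``).
    """

    root: PhyloNode
    name: str = "marker-tree"

    def __post_init__(self) -> None:
        names = [n.name for n in self.root.walk()]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise InvalidArgument(f"duplicate node names in marker tree: {dupes}")

    def node(self, name: str) -> PhyloNode:
        found = self.root.find(name)
        if found is None:
            raise InvalidArgument(f"no haplogroup named {name!r} in tree")
        return found

    def nodes(self) -> list[PhyloNode]:
        return list(self.root.walk())


# ---------------------------------------------------------------------------
# Y-STR haplotypes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StrHaplotype:
    """A Y-STR haplotype: per-locus repeat counts plus a carrier count."""

    loci: tuple[str, ...]
    repeats: tuple[int, ...]
    count: int = 1
    population: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.loci) != len(self.repeats):
            raise InvalidArgument("loci and repeats length mismatch")
        if len(self.loci) == 0:
            raise InvalidArgument("haplotype must have at least one locus")
        if any(r < 1 for r in self.repeats):
            raise InvalidArgument("repeat counts must be >= 1")

    def with_repeats(self, repeats: Sequence[int], count: int = 1) -> "StrHaplotype":
        return StrHaplotype(self.loci, tuple(int(r) for r in repeats), count=count)


# ---------------------------------------------------------------------------
# Genotype matrices
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Diploid genotypes as minor-allele dosages.

    ``calls`` is ``n_samples x n_snps`` int8 with values {0, 1, 2} and
    :data:`MISSING` (-1) for no-calls.
    """

    calls: np.ndarray
    sample_ids: list[str]
    populations: list[str]
    snp_ids: list[str]
    chromosomes: np.ndarray
    positions: np.ndarray
    alleles: Optional[list[tuple[str, str]]] = None  # (minor, major) per SNP

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.chromosomes = np.asarray(self.chromosomes, dtype=int)
        self.positions = np.asarray(self.positions, dtype=int)
        n, L = self.calls.shape
        if len(self.sample_ids) != n or len(self.populations) != n:
            raise InvalidArgument("sample metadata length != number of rows")
        if not (len(self.snp_ids) == len(self.chromosomes) == len(self.positions) == L):
            raise InvalidArgument("SNP metadata length != number of columns")

    @property
    def n_samples(self) -> int:
        return self.calls.shape[0]

    @property
    def n_snps(self) -> int:
        return self.calls.shape[1]

    def called_mask(self) -> np.ndarray:
        return self.calls != MISSING

    def dosage_float(self) -> np.ndarray:
        """Calls as float with NaN for missing."""
        g = self.calls.astype(float)
        g[self.calls == MISSING] = np.nan
        return g

    def minor_allele_freq(self) -> np.ndarray:
        g = self.dosage_float()
        with np.errstate(invalid="ignore"):
            p = np.nanmean(g, axis=0) / 2.0
        return np.minimum(p, 1.0 - p)

    def call_rate(self) -> np.ndarray:
        return self.called_mask().mean(axis=0)

    def subset(self, sample_idx=None, snp_idx=None) -> "GenotypeMatrix":
        si = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        vi = np.arange(self.n_snps) if snp_idx is None else np.asarray(snp_idx)
        return GenotypeMatrix(
            calls=self.calls[np.ix_(si, vi)],
            sample_ids=[self.sample_ids[i] for i in si],
            populations=[self.populations[i] for i in si],
            snp_ids=[self.snp_ids[j] for j in vi],
            chromosomes=self.chromosomes[vi],
            positions=self.positions[vi],
            alleles=None if self.alleles is None else [self.alleles[j] for j in vi],
        )


# ---------------------------------------------------------------------------
# Distance matrices
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    """Labelled symmetric non-negative matrix with zero diagonal."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise InvalidArgument("matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise InvalidArgument("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise InvalidArgument("distance matrix diagonal must be zero")
        # enforce exact symmetry / zero diagonal after tolerance check
        self.values = (self.values + self.values.T) / 2.0
        np.fill_diagonal(self.values, 0.0)

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        """Upper-triangle (off-diagonal) entries, row-major."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def reorder(self, labels: Sequence[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)])


# ---------------------------------------------------------------------------
# Result records
# ---------------------------------------------------------------------------

@dataclass
class AgeEstimate:
    rho: float
    sigma: float
    years: float
    ci95: tuple[float, float]
    rate_mu: float
    seq_length: int


@dataclass
class AdmixtureFit:
    K: int
    Q: np.ndarray
    F: np.ndarray
    loglik: float
    seed: int
    n_iter: int
    ll_trace: list[float] = field(default_factory=list)


@dataclass
class FstMatrix:
    labels: list[str]
    values: np.ndarray  # pairwise W&C estimates; diagonal 0; may be slightly negative

    def to_distance_matrix(self, clip_negative: bool = True) -> DistanceMatrix:
        v = self.values.copy()
        if clip_negative:
            v = np.maximum(v, 0.0)
        np.fill_diagonal(v, 0.0)
        return DistanceMatrix(list(self.labels), v)


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    partial: bool = False
    controlled_labels: Optional[str] = None
    exhaustive: bool = False

    @property
    def variance_explained_pct(self) -> float:
        return 100.0 * self.r ** 2


# ---------------------------------------------------------------------------
# Simulation outputs
# ---------------------------------------------------------------------------

@dataclass
class SimStarClade:
    n_tips: int
    expected_subs: float
    tree: PhyloNode
    haplotypes: list[frozenset[str]]


@dataclass
class SimAdmixedCohort:
    Q_true: np.ndarray
    F_true: np.ndarray
    genotypes: GenotypeMatrix
    fst_param: float
    dirichlet_alpha: np.ndarray


def as_variant_tokens(variants: Iterable) -> frozenset[str]:
    """Normalise a mixed iterable of Variant objects / strings to tokens."""
    out = set()
    for v in variants:
        out.add(v.token if isinstance(v, Variant) else str(v))
    return frozenset(out)
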