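"""mtDNA variant parsing, haplogroup classification, and rho-based dating.

Variant notation follows the conventions used for human mtDNA phylogenies
against the rCRS/RSRS references:

* ``A11252G`` / ``16189C`` — substitutions; capital letters are transitions,
  lowercase letters transversions;
* a trailing ``!`` marks a reversal (back-mutation) to the ancestral state;
* ``315.1C`` — insertion of C after np 315 (first inserted base);
* ``16166d`` — deletion of np 16166;
* IUPAC ambiguity codes (e.g. ``73R``) mark heteroplasmic positions, which
  are treated as missing data for classification and substitution counts.

Classification walks a rooted marker tree whose edges carry defining
variants; the same machinery serves Y biallelic marker trees, where the
"variants" are marker names such as ``M217``. Clade ages come from the rho
statistic (mean substitutions from the clade root over sampled tips) with
the Saillard-type standard error, converted to years with a linear
molecular clock.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional, Sequence

import numpy as np
import yaml

from .core import (
    AgeEstimate,
    HaplogroupTree,
    InvalidArgument,
    IUPAC_AMBIGUOUS,
    ParseError,
    PhyloNode,
    Variant,
)

MT_LENGTH = 16569

# default per-nucleotide per-year substitution rate for the whole molecule
DEFAULT_MT_RATE = 1.665e-8
DEFAULT_MT_RATE_SD = 1.479e-9

TRANSITIONS = {frozenset("AG"), frozenset("CT")}

_SUB_FULL = re.compile(r"^([ACGTacgt])(\d+)([A-Za-z])(!?)$")
_SUB_SHORT = re.compile(r"^(\d+)([A-Za-z])(!?)$")
_INSERTION = re.compile(r"^(\d+)\.(\d+)([ACGTacgt]+)$")
_DELETION = re.compile(r"^([ACGTacgt]?)(\d+)d(!?)$")


def _check_position(pos: int, token: str) -> None:
    if not 1 <= pos <= MT_LENGTH:
        raise ParseError(f"position {pos} out of range in token {token!r}")


def parse_variant(token: str) -> Variant:
    """Parse one variant token into a :class:`~arcticpop.core.Variant`.

    Raises :class:`ParseError` naming the token if it cannot be parsed.
    """
    tok = token.strip()
    if not tok:
        raise ParseError("empty variant token")

    m = _INSERTION.match(tok)
    if m:
        pos, idx, bases = int(m.group(1)), int(m.group(2)), m.group(3)
        _check_position(pos, tok)
        return Variant(position=pos, kind="insertion", alt=bases.upper(),
                       insert_index=idx)

    m = _DELETION.match(tok)
    if m:
        ref, pos, bang = m.group(1) or None, int(m.group(2)), bool(m.group(3))
        _check_position(pos, tok)
        return Variant(position=pos, kind="deletion", ref=ref,
                       back_mutation=bang)

    m = _SUB_FULL.match(tok)
    if m:
        ref, pos, alt, bang = m.group(1), int(m.group(2)), m.group(3), bool(m.group(4))
        _check_position(pos, tok)
        return _substitution(pos, ref, alt, bang, tok)

    m = _SUB_SHORT.match(tok)
    if m:
        pos, alt, bang = int(m.group(1)), m.group(2), bool(m.group(3))
        _check_position(pos, tok)
        return _substitution(pos, None, alt, bang, tok)

    raise ParseError(f"unparseable variant token {token!r}")


def _substitution(pos: int, ref: Optional[str], alt: str, bang: bool,
                  token: str) -> Variant:
    if alt.upper() in IUPAC_AMBIGUOUS and alt.isupper():
        return Variant(position=pos, kind="heteroplasmy", ref=ref, alt=alt)
    if alt.upper() not in "ACGT":
        raise ParseError(f"unknown base {alt!r} in token {token!r}")
    if ref is not None:
        kind = ("transition"
                if frozenset((ref.upper(), alt.upper())) in TRANSITIONS
                else "transversion")
        # preserve the notational case convention on the stored alt
        alt_stored = alt.upper() if kind == "transition" else alt.lower()
    else:
        # case convention: capital = transition, lowercase = transversion
        kind = "transition" if alt.isupper() else "transversion"
        alt_stored = alt
    return Variant(position=pos, kind=kind, ref=ref.upper() if ref else None,
                   alt=alt_stored, back_mutation=bang)


def parse_variant_list(text: str) -> list[Variant]:
    """Parse a whitespace-separated variant string (one sample's genotype)."""
    return [parse_variant(t) for t in text.split()]


# ---------------------------------------------------------------------------
# Site-exclusion filtering
# ---------------------------------------------------------------------------

@dataclass
class ExclusionPolicy:
    """Which sites/events are ignored for phylogeny and haplotype identity.

    Defaults: the hypervariable site 16519; length variation (insertions and
    deletions) in the poly-C stretches 303-315 and 16184-16194; and A-C
    transversions at 16182/16183 whenever the C-T transition at 16189 is
    present in the same haplotype (they depend on it).
    """

    excluded_sites: frozenset[int] = frozenset({16519})
    length_variant_ranges: tuple[tuple[int, int], ...] = ((303, 315), (16184, 16194))
    conditional_transversions: tuple[int, ...] = (16182, 16183)
    conditional_trigger_site: int = 16189
    drop_heteroplasmies: bool = True

    def _in_length_range(self, pos: int) -> bool:
        return any(lo <= pos <= hi for lo, hi in self.length_variant_ranges)

    def apply(self, variants: Iterable[Variant]) -> list[Variant]:
        vs = list(variants)
        trigger = any(
            v.kind == "transition" and v.position == self.conditional_trigger_site
            and not v.back_mutation
            for v in vs
        )
        out = []
        for v in vs:
            if v.position in self.excluded_sites:
                continue
            if v.kind in ("insertion", "deletion") and self._in_length_range(v.position):
                continue
            if (trigger and v.kind == "transversion"
                    and v.position in self.conditional_transversions
                    and (v.alt or "").upper() == "C"):
                continue
            if self.drop_heteroplasmies and v.kind == "heteroplasmy":
                continue
            out.append(v)
        return out


DEFAULT_POLICY = ExclusionPolicy()


def exclusion_filter(variants: Iterable[Variant],
                     policy: ExclusionPolicy = DEFAULT_POLICY) -> list[Variant]:
    """Return the variants that survive the site-exclusion policy."""
    return policy.apply(variants)


# ---------------------------------------------------------------------------
# Marker-tree classification
# ---------------------------------------------------------------------------

@dataclass
class Classification:
    haplogroup: str
    path: list[str]
    unexplained: frozenset[str]


def _node_requirements(node: PhyloNode) -> tuple[frozenset[str], frozenset[str]]:
    """Cumulative (required-present, required-absent) token sets for a node.

    Walking root->node, each edge token adds its base token to the expected
    state; a ``!``-suffixed token removes the base token (reversal) and
    requires its absence.
    """
    present: set[str] = set()
    absent: set[str] = set()
    for n in node.path_from_root()[1:]:
        for tok in n.edge_variants:
            if tok.endswith("!"):
                base = tok[:-1]
                present.discard(base)
                absent.add(base)
            else:
                present.add(tok)
                absent.discard(tok)
    return frozenset(present), frozenset(absent)


_POS_PREFIX = re.compile(r"^[ACGTacgt]?(\d+)")


def _token_position(tok: str) -> Optional[int]:
    m = _POS_PREFIX.match(tok)
    return int(m.group(1)) if m else None


def normalize_tokens(variants: Iterable) -> tuple[frozenset[str], frozenset[int]]:
    """Observed state of a haplotype as base tokens, plus heteroplasmic sites.

    Back-mutated tokens contribute nothing (the site shows the ancestral
    state); heteroplasmies are collected as missing positions.
    """
    state: set[str] = set()
    bangs: set[str] = set()
    het: set[int] = set()
    for v in variants:
        if isinstance(v, Variant):
            if v.kind == "heteroplasmy":
                het.add(v.position)
                continue
            if v.back_mutation:
                bangs.add(v.base_token)
                continue
            state.add(v.token)
        else:
            tok = str(v)
            if tok.endswith("!"):
                bangs.add(tok[:-1])
                continue
            state.add(tok)
    # a reversal cancels the forward token if the list carries both
    return frozenset(state - bangs), frozenset(het)


def _strip_anchor(tok: str) -> str:
    """Drop a leading reference base so 'A11252G' and '11252G' compare equal."""
    m = re.match(r"^[ACGTacgt](\d+.+)$", tok)
    return m.group(1) if m else tok


def classify_by_marker_tree(variants: Iterable, tree: HaplogroupTree):
    """Assign the deepest haplogroup whose defining variants are all present.

    Back-mutations on the path toggle the expected state, and the reversal
    itself counts as a confirmed marker: candidates are ranked by the
    number of satisfied marker requirements (present + required-absent),
    which equals path depth in variants for ordinary nested clades but
    keeps reversal-defined clades from outranking siblings they do not
    actually explain. Ties break by fewest unexplained private variants,
    then name order. Returns a :class:`Classification`.
    """
    state, het_positions = normalize_tokens(variants)
    state = frozenset(_strip_anchor(t) for t in state)
    state_positions = {t: _token_position(t) for t in state}

    best: Optional[tuple[int, int, str, PhyloNode, frozenset[str]]] = None
    for node in tree.nodes():
        present_req, absent_req = _node_requirements(node)
        present_req = frozenset(_strip_anchor(t) for t in present_req)
        absent_req = frozenset(_strip_anchor(t) for t in absent_req)
        ok = True
        for tok in present_req:
            pos = _token_position(tok)
            if pos is not None and pos in het_positions:
                continue  # heteroplasmic site: cannot confirm or deny
            if tok not in state:
                ok = False
                break
        if ok:
            for tok in absent_req:
                pos = _token_position(tok)
                if pos is not None and pos in het_positions:
                    continue
                if tok in state:
                    ok = False
                    break
        if not ok:
            continue
        confirmed = len(present_req) + len(absent_req)
        unexplained = frozenset(t for t in state if t not in present_req)
        key = (-confirmed, len(unexplained), node.name)
        if best is None or key < (best[0], best[1], best[2]):
            best = (key[0], key[1], key[2], node, unexplained)

    if best is None:  # root always matches (empty requirements) — defensive
        node = tree.root
        unexplained = state
    else:
        node, unexplained = best[3], best[4]
    return Classification(
        haplogroup=node.name,
        path=[n.name for n in node.path_from_root()],
        unexplained=unexplained,
    )


# ---------------------------------------------------------------------------
# Marker-tree config IO
# ---------------------------------------------------------------------------

def load_marker_tree(path_or_stream) -> HaplogroupTree:
    """Load a marker tree from a YAML config.

    Schema::

        name: <tree name>
        root: <root node name>
        nodes:
          <name>: {parent: <name>, variants: [tok, tok, ...]}
    """
    if hasattr(path_or_stream, "read"):
        cfg = yaml.safe_load(path_or_stream)
    else:
        with open(path_or_stream) as fh:
            cfg = yaml.safe_load(fh)
    root_name = cfg["root"]
    nodes = {root_name: PhyloNode(name=root_name)}
    entries = cfg.get("nodes", {}) or {}
    pending = dict(entries)
    # attach nodes in dependency order
    while pending:
        progressed = False
        for name in list(pending):
            spec = pending[name]
            parent = spec.get("parent")
            if parent in nodes:
                variants = tuple(str(v) for v in (spec.get("variants") or []))
                node = PhyloNode(name=name, edge_variants=variants,
                                 edge_count=len(variants))
                nodes[parent].add_child(node)
                nodes[name] = node
                del pending[name]
                progressed = True
        if not progressed:
            raise InvalidArgument(
                f"marker tree config has orphan/cyclic nodes: {sorted(pending)}")
    return HaplogroupTree(root=nodes[root_name], name=cfg.get("name", "marker-tree"))


def default_mt_tree() -> HaplogroupTree:
    """The bundled (synthetic-marker) mtDNA haplogroup tree."""
    with resources.files("arcticpop.data").joinpath(
            "mt_marker_tree_synthetic.yaml").open() as fh:
        return load_marker_tree(fh)


def default_y_tree() -> HaplogroupTree:
    """The bundled (synthetic-hierarchy) Y biallelic marker tree."""
    with resources.files("arcticpop.data").joinpath(
            "y_marker_tree_synthetic.yaml").open() as fh:
        return load_marker_tree(fh)


# ---------------------------------------------------------------------------
# Haplotype spectrum
# ---------------------------------------------------------------------------

@dataclass
class SpectrumResult:
    n_haplotypes: int
    n_subhaplogroups: int
    frequency_table: "object"       # pandas DataFrame: pop x haplogroup, rows sum to 1
    classifications: dict[str, str]  # sample_id -> haplogroup
    unclassified: list[str] = field(default_factory=list)


HVSI_RANGE = (16017, 16399)


def haplotype_spectrum(table, tree: HaplogroupTree,
                       policy: ExclusionPolicy = DEFAULT_POLICY,
                       mode: str = "all",
                       pool_map: Optional[dict[str, str]] = None) -> SpectrumResult:
    """Classify every sample and count distinct haplotypes/sub-haplogroups.

    ``table`` is a :class:`~arcticpop.formats_io.MtHaplotypeTable`.
    Haplotype identity is post-filter variant-set equality; ``mode='hvsi'``
    restricts identity to variants inside the HVSI range (np 16017-16399),
    ``mode='all'`` uses the full variant set. ``pool_map`` merges population
    codes before frequencies are computed (e.g. pooling Dolgan samples from
    Sakha and Taymyr).
    """
    import pandas as pd

    if mode not in ("all", "hvsi"):
        raise InvalidArgument(f"unknown spectrum mode {mode!r}")

    haplotype_keys: set[frozenset[str]] = set()
    classes: dict[str, str] = {}
    rows = []
    unclassified: list[str] = []
    for rec in table.records:
        variants = policy.apply(rec.variants)
        try:
            cls = classify_by_marker_tree(variants, tree)
        except Exception:
            unclassified.append(rec.sample_id)
            continue
        if mode == "hvsi":
            ident = [v for v in variants
                     if HVSI_RANGE[0] <= v.position <= HVSI_RANGE[1]]
        else:
            ident = variants
        haplotype_keys.add(frozenset(v.token for v in ident))
        pop = rec.population
        if pool_map and pop in pool_map:
            pop = pool_map[pop]
        classes[rec.sample_id] = cls.haplogroup
        rows.append((pop, cls.haplogroup))

    df = pd.DataFrame(rows, columns=["population", "haplogroup"])
    if len(df):
        freq = (df.groupby(["population", "haplogroup"]).size()
                  .unstack(fill_value=0))
        freq = freq.div(freq.sum(axis=1), axis=0)
    else:
        freq = pd.DataFrame()
    return SpectrumResult(
        n_haplotypes=len(haplotype_keys),
        n_subhaplogroups=len(set(classes.values())),
        frequency_table=freq,
        classifications=classes,
        unclassified=unclassified,
    )


# ---------------------------------------------------------------------------
# Haplotype tree reconstruction (greedy perfect phylogeny)
# ---------------------------------------------------------------------------

def reconstruct_haplotype_tree(haplotypes: Sequence[Iterable],
                               root: Iterable = ()) -> PhyloNode:
    """Build a rooted tree from haplotype variant sets by greedy grouping.

    Haplotypes are variant-token sets relative to the given root state.
    Shared derived variants group haplotypes under common edges (most
    frequent variant first); a variant incompatible with a single placement
    recurs on several edges and is flagged on the root's ``recurrent``
    attribute. Every input haplotype becomes a leaf; the substitution counts
    along a leaf's root path sum to its variant distance from the root.
    """
    root_set = frozenset(str(t) for t in root)
    sets = [frozenset(str(t) for t in h) - root_set for h in haplotypes]

    placements: dict[str, int] = {}
    root_node = PhyloNode(name="root")
    counter = [0]

    def build(parent: PhyloNode, items: list[tuple[int, frozenset[str]]],
              prefix: frozenset[str]) -> None:
        # haplotypes identical to the current ancestor become zero-length tips
        here = [(i, s) for i, s in items if not s]
        rest = [(i, s) for i, s in items if s]
        for i, _ in here:
            tip = PhyloNode(name=f"H{i}", edge_count=0, n_samples=1)
            parent.add_child(tip)
        while rest:
            counts: dict[str, int] = {}
            for _, s in rest:
                for tok in s:
                    counts[tok] = counts.get(tok, 0) + 1
            # deterministic: highest carrier count, then token order
            pivot = min(counts, key=lambda t: (-counts[t], t))
            carriers = [(i, s) for i, s in rest if pivot in s]
            rest = [(i, s) for i, s in rest if pivot not in s]
            # extend the edge by every variant shared by all carriers
            shared = frozenset.intersection(*(s for _, s in carriers))
            edge = tuple(sorted(shared))
            for tok in edge:
                placements[tok] = placements.get(tok, 0) + 1
            counter[0] += 1
            child = PhyloNode(name=f"n{counter[0]}", edge_variants=edge,
                              edge_count=len(edge))
            parent.add_child(child)
            build(child, [(i, s - shared) for i, s in carriers], prefix | shared)

    build(root_node, list(enumerate(sets)), frozenset())
    root_node.recurrent = tuple(sorted(t for t, c in placements.items() if c > 1))
    return root_node


# ---------------------------------------------------------------------------
# Rho statistic and dating
# ---------------------------------------------------------------------------

def rho_statistic(tree: PhyloNode, clade: Optional[str] = None) -> tuple[float, float]:
    """Mean substitutions from the clade root to its tips, and its SE.

    rho is the arithmetic mean of root-to-tip substitution counts; the
    standard error follows the genealogy-aware estimator
    sigma^2 = sum_e (n_e / n)^2 * l_e, where n_e is the number of tips below
    edge e and l_e its substitution count.
    """
    node = tree if clade is None else tree.find(clade)
    if node is None:
        raise InvalidArgument(f"clade {clade!r} not found")
    tips = node.tips()
    if not tips:
        raise InvalidArgument("clade has no tips")
    n = len(tips)

    def subtree_stats(nd: PhyloNode) -> tuple[int, float, float]:
        """(tips below, sum of root->tip counts, sigma^2 contribution)."""
        if not nd.children:
            return 1, 0.0, 0.0
        n_below, total, var = 0, 0.0, 0.0
        for c in nd.children:
            nb, tot, vr = subtree_stats(c)
            n_below += nb
            total += tot + nb * c.edge_count
            var += vr + (nb / n) ** 2 * c.edge_count
        return n_below, total, var

    _, total, var = subtree_stats(node)
    return total / n, float(np.sqrt(var))


def age_from_rho(rho: float, sigma: float = 0.0,
                 rate_mu: float = DEFAULT_MT_RATE,
                 seq_length: int = MT_LENGTH) -> AgeEstimate:
    """Convert rho to years with a linear molecular clock.

    years = rho / (rate_mu * seq_length); the 95% CI comes from
    rho +/- 1.96 sigma, clipped at zero.
    """
    if rho < 0:
        raise InvalidArgument("rho must be non-negative")
    if rate_mu <= 0 or seq_length <= 0:
        raise InvalidArgument("mutation rate and sequence length must be positive")
    denom = rate_mu * seq_length
    years = rho / denom
    lo = max(0.0, (rho - 1.96 * sigma)) / denom
    hi = (rho + 1.96 * sigma) / denom
    return AgeEstimate(rho=rho, sigma=sigma, years=years, ci95=(lo, hi),
                       rate_mu=rate_mu, seq_length=seq_length)
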