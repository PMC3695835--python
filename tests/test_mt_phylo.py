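"""mtDNA variant parsing, classification, spectra, and rho dating."""

import itertools

import numpy as np
import pytest

from arcticpop import mt_phylo as mp
from arcticpop import synthdata
from arcticpop.core import ParseError, PhyloNode, InvalidArgument


# ---------------------------------------------------------------------------
# Variant parsing
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("token, position, kind, back", [
    ("A11252G", 11252, "transition", False),
    ("G7521A", 7521, "transition", False),
    ("16189C", 16189, "transition", False),
    ("16182c", 16182, "transversion", False),
    ("3552a", 3552, "transversion", False),
    ("C16298T", 16298, "transition", False),
    ("T3306C", 3306, "transition", False),
    ("16189C!", 16189, "transition", True),
    ("G7521A!", 7521, "transition", True),
    ("523.1C", 523, "insertion", False),
    ("315.1C", 315, "insertion", False),
    ("16166d", 16166, "deletion", False),
    ("73R", 73, "heteroplasmy", False),
])
def test_parse_variant_forms(token, position, kind, back):
    v = mp.parse_variant(token)
    assert v.position == position
    assert v.kind == kind
    assert v.back_mutation == back


def test_transition_vs_transversion_from_anchored_form():
    assert mp.parse_variant("A11252G").kind == "transition"  # A<->G
    assert mp.parse_variant("A11252C").kind == "transversion"  # A<->C


@pytest.mark.parametrize("bad", ["", "XYZ", "99999A", "12345Q", "A0G"])
def test_parse_variant_rejects_garbage(bad):
    with pytest.raises(ParseError):
        mp.parse_variant(bad)


def test_parse_error_names_token():
    with pytest.raises(ParseError, match="16570"):
        mp.parse_variant("16570A")


# ---------------------------------------------------------------------------
# Exclusion filtering
# ---------------------------------------------------------------------------

def toks(*ts):
    return [mp.parse_variant(t) for t in ts]


def test_site_16519_excluded():
    assert mp.exclusion_filter(toks("16519T")) == []


def test_conditional_16182_16183_transversions():
    out = mp.exclusion_filter(toks("16182c", "16189C"))
    assert [v.token for v in out] == ["16189C"]
    # without the 16189 transition the transversion survives
    out2 = mp.exclusion_filter(toks("16182c"))
    assert [v.token for v in out2] == ["16182c"]


def test_polyc_length_variants_excluded_but_substitutions_kept():
    out = mp.exclusion_filter(toks("315.1C", "16188.1C", "310C", "16186T"))
    assert sorted(v.token for v in out) == ["16186T", "310C"]


def test_non_excluded_site_passes():
    out = mp.exclusion_filter(toks("T3306C"))
    assert [v.token for v in out] == ["3306C"]


def test_empty_in_empty_out():
    assert mp.exclusion_filter([]) == []


# ---------------------------------------------------------------------------
# Marker-tree classification
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def mt_tree():
    return mp.default_mt_tree()


def path_tokens(tree, name):
    out = []
    for nd in tree.node(name).path_from_root()[1:]:
        out.extend(nd.edge_variants)
    return out


def test_classify_terminal_clades(mt_tree):
    assert mp.classify_by_marker_tree(
        path_tokens(mt_tree, "C4b") + ["3306C"], mt_tree).haplogroup == "C4b9"
    assert mp.classify_by_marker_tree(
        path_tokens(mt_tree, "Z1a") + ["14002C", "7521A", "8251A"],
        mt_tree).haplogroup == "Z1a1b"


def test_classify_back_mutation_defined_clade(mt_tree):
    # C5a2a is defined by the reversal of 16189C carried by C5a2
    c5a2a = [t for t in path_tokens(mt_tree, "C5a2a")]
    assert mp.classify_by_marker_tree(c5a2a, mt_tree).haplogroup == "C5a2a"
    c5a2 = path_tokens(mt_tree, "C5a2")
    assert mp.classify_by_marker_tree(c5a2, mt_tree).haplogroup == "C5a2"


def test_empty_variant_set_is_root(mt_tree):
    assert mp.classify_by_marker_tree([], mt_tree).haplogroup == "mt-MRCA"


def test_classification_idempotent_and_private_variant_inert(mt_tree):
    base = path_tokens(mt_tree, "D5a2a2")
    first = mp.classify_by_marker_tree(base, mt_tree)
    assert first.haplogroup == "D5a2a2"
    # re-classifying the defining variants reproduces the call
    again = mp.classify_by_marker_tree(base, mt_tree)
    assert again.haplogroup == first.haplogroup
    # a private variant at a position the tree never uses changes nothing
    assert mp.classify_by_marker_tree(
        base + ["16111T"], mt_tree).haplogroup == "D5a2a2"


def test_heteroplasmy_does_not_block_classification(mt_tree):
    base = path_tokens(mt_tree, "C4a2")
    # replace one defining marker with a heteroplasmic observation there
    partial = [t for t in base if t != "8584A"] + ["8584R"]
    variants = [mp.parse_variant(t) for t in partial]
    assert mp.classify_by_marker_tree(variants, mt_tree).haplogroup == "C4a2"


def test_classifier_works_on_y_marker_tree():
    ytree = mp.default_y_tree()
    assert mp.classify_by_marker_tree(
        ["M89", "M9", "M231", "TAT"], ytree).haplogroup == "N1c"
    assert mp.classify_by_marker_tree(
        ["M130", "M217", "M48"], ytree).haplogroup == "C3c"


# ---------------------------------------------------------------------------
# Haplotype spectrum
# ---------------------------------------------------------------------------

def make_table(rows):
    from arcticpop.formats_io import MtHaplotypeTable, MtRecord
    recs = [MtRecord(sample_id=f"S{i}", population=pop,
                     variants=mp.parse_variant_list(v), raw_variants=v)
            for i, (pop, v) in enumerate(rows)]
    return MtHaplotypeTable(recs)


def test_identical_rows_collapse(mt_tree):
    v = " ".join(path_tokens(mt_tree, "C4b9"))
    table = make_table([("CY", v)] * 5)
    res = mp.haplotype_spectrum(table, mt_tree)
    assert (res.n_haplotypes, res.n_subhaplogroups) == (1, 1)


def test_excluded_site_difference_is_one_haplotype(mt_tree):
    v = " ".join(path_tokens(mt_tree, "C4b9"))
    table = make_table([("CY", v), ("CY", v + " 16519T")])
    res = mp.haplotype_spectrum(table, mt_tree)
    assert res.n_haplotypes == 1


def test_spectrum_invariant_to_row_order(mt_tree):
    rows = [("CY", " ".join(path_tokens(mt_tree, "C4b9"))),
            ("EK", " ".join(path_tokens(mt_tree, "Z1a3"))),
            ("CY", " ".join(path_tokens(mt_tree, "D5a2a2")))]
    r1 = mp.haplotype_spectrum(make_table(rows), mt_tree)
    r2 = mp.haplotype_spectrum(make_table(rows[::-1]), mt_tree)
    assert r1.n_haplotypes == r2.n_haplotypes
    assert r1.n_subhaplogroups == r2.n_subhaplogroups


def test_frequency_rows_sum_to_one_and_pooling(mt_tree):
    rows = [("DL_S", " ".join(path_tokens(mt_tree, "C4b9"))),
            ("DL_T", " ".join(path_tokens(mt_tree, "Z1a1b"))),
            ("CY", " ".join(path_tokens(mt_tree, "D5a2a2")))]
    res = mp.haplotype_spectrum(make_table(rows), mt_tree,
                                pool_map={"DL_S": "DL", "DL_T": "DL"})
    ft = res.frequency_table
    assert set(ft.index) == {"DL", "CY"}
    assert np.allclose(ft.sum(axis=1), 1.0)


# ---------------------------------------------------------------------------
# Haplotype tree reconstruction
# ---------------------------------------------------------------------------

def test_star_data_gives_star_tree():
    haps = [{"1A"}, {"2C"}, {"3G"}]
    tree = mp.reconstruct_haplotype_tree(haps)
    # every sampled haplotype hangs off the root through its own edge
    assert len(tree.children) == 3
    assert tree.recurrent == ()


def test_nested_haplotypes_give_chain():
    a = {"10A"}
    b = {"10A", "20C"}
    tree = mp.reconstruct_haplotype_tree([a, b])
    depths = sorted(t.depth_count() for t in tree.tips())
    assert depths == [1, 2]


def test_leaf_path_counts_equal_variant_distance():
    rng = np.random.default_rng(5)
    for _ in range(20):
        n = rng.integers(2, 8)
        haps = []
        pool = [f"{p}A" for p in range(1, 40)]
        for _ in range(n):
            k = rng.integers(0, 6)
            haps.append(set(rng.choice(pool, size=k, replace=False)))
        tree = mp.reconstruct_haplotype_tree(haps)
        tips = sorted(tree.tips(), key=lambda t: t.name)
        by_name = {t.name: t for t in tree.tips()}
        for i, h in enumerate(haps):
            assert by_name[f"H{i}"].depth_count() == len(h)


def test_reconstruction_matches_perfect_phylogeny_oracle():
    """On compatible 4-tip data, the greedy tree attains the perfect-
    phylogeny parsimony score: every variant placed exactly once."""
    rng = np.random.default_rng(11)
    for _ in range(25):
        # simulate on a random nested structure => compatible by construction
        v = [f"{p}A" for p in rng.choice(np.arange(1, 200), 8, replace=False)]
        h1 = {v[0]}
        h2 = {v[0], v[1]}
        h3 = {v[2], v[3]}
        h4 = {v[2], v[4], v[5]}
        tree = mp.reconstruct_haplotype_tree([h1, h2, h3, h4])
        total_placements = sum(n.edge_count for n in tree.walk())
        distinct = len(h1 | h2 | h3 | h4)
        assert total_placements == distinct  # no recurrent placements needed
        assert tree.recurrent == ()


def test_incompatible_variants_flagged_recurrent():
    # four-gamete violation: 1A/2C present in all combinations
    haps = [{"1A"}, {"2C"}, {"1A", "2C"}, set()]
    tree = mp.reconstruct_haplotype_tree(haps)
    # all patterns representable without recurrence here (nested), so force:
    haps = [{"1A", "3G"}, {"2C", "3G"}, {"1A", "2C"}]
    tree = mp.reconstruct_haplotype_tree(haps)
    assert len(tree.recurrent) >= 1


# ---------------------------------------------------------------------------
# Rho and dating
# ---------------------------------------------------------------------------

def star_tree(counts):
    root = PhyloNode("root")
    for i, k in enumerate(counts):
        root.add_child(PhyloNode(f"t{i}", edge_count=k, n_samples=1))
    return root


def test_rho_star_hand_case():
    rho, sigma = mp.rho_statistic(star_tree([1, 2, 3]))
    assert rho == pytest.approx(2.0)
    assert sigma == pytest.approx(np.sqrt(6 / 9), abs=1e-12)


def test_rho_zero_for_unmutated_tips():
    rho, sigma = mp.rho_statistic(star_tree([0, 0, 0]))
    assert (rho, sigma) == (0.0, 0.0)


def test_rho_on_structured_tree_matches_direct_mean():
    # two cherries: rho must average full root->tip path counts
    root = PhyloNode("root")
    a = root.add_child(PhyloNode("a", edge_count=2))
    a.add_child(PhyloNode("a1", edge_count=1))
    a.add_child(PhyloNode("a2", edge_count=3))
    root.add_child(PhyloNode("b", edge_count=4))
    rho, sigma = mp.rho_statistic(root)
    assert rho == pytest.approx((3 + 5 + 4) / 3)
    # sigma^2 = (2/3)^2*2 + (1/3)^2*1 + (1/3)^2*3 + (1/3)^2*4
    assert sigma ** 2 == pytest.approx((4 / 9) * 2 + (1 + 3 + 4) / 9)


def test_rho_empty_clade_errors():
    with pytest.raises(InvalidArgument):
        mp.rho_statistic(star_tree([1]), clade="nope")


def test_age_hand_values():
    assert mp.age_from_rho(0.0).years == 0.0
    assert mp.age_from_rho(1.0).years == pytest.approx(3624.8, abs=0.1)
    assert mp.age_from_rho(2.593).years == pytest.approx(9399.2, abs=0.1)


@pytest.mark.parametrize("rho", [0.5, 1.0, 2.0])
def test_age_linear_in_rho_and_inverse_in_rate_and_length(rho):
    base = mp.age_from_rho(rho).years
    assert mp.age_from_rho(2 * rho).years == pytest.approx(2 * base)
    assert mp.age_from_rho(rho, rate_mu=2 * mp.DEFAULT_MT_RATE).years \
        == pytest.approx(base / 2)
    assert mp.age_from_rho(rho, seq_length=2 * mp.MT_LENGTH).years \
        == pytest.approx(base / 2)


def test_age_ci_uses_sigma_and_clips_at_zero():
    est = mp.age_from_rho(1.0, sigma=1.0)
    assert est.ci95[0] == 0.0
    assert est.ci95[1] == pytest.approx((1 + 1.96) / (mp.DEFAULT_MT_RATE * mp.MT_LENGTH))


def test_age_invalid_rate_errors():
    with pytest.raises(InvalidArgument):
        mp.age_from_rho(1.0, rate_mu=0.0)


def test_rho_zero_rate_star_clade():
    clade = synthdata.sim_star_clade(3, 0.0, seed=1)
    rho, sigma = mp.rho_statistic(clade.tree)
    assert (rho, sigma) == (0.0, 0.0)
    assert all(h == frozenset() for h in clade.haplotypes)
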