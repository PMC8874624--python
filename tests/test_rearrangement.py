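"""Gene-order canonicalization, typing, event inference and tree mapping."""

import math

import dendropy
import numpy as np
import pytest

from mitocompare.mitio import GeneOrder
from mitocompare.rearrangement import (
    DERIVED_FEATURES,
    ancestral_order,
    breakpoint_distance,
    canonicalize,
    classify_types,
    infer_events,
    map_types_on_tree,
    r1_order,
)
from mitocompare.synthetic_data import (
    R1_EVENTS,
    TRNL2_TRANSPOSITION,
    SimulationConfig,
    _random_events,
    apply_events,
    simulate_gene_orders,
)


def rotate(order: GeneOrder, k: int) -> GeneOrder:
    e = order.elements
    return GeneOrder(order.genome_id, e[k:] + e[:k])


def reflect(order: GeneOrder) -> GeneOrder:
    return GeneOrder(
        order.genome_id, tuple((g, -s) for g, s in reversed(order.elements))
    )


# --- canonical signatures ----------------------------------------------------

def test_signature_invariant_to_rotation(ancestral):
    keys = {canonicalize(rotate(ancestral, k)).key for k in range(0, 37, 5)}
    assert len(keys) == 1


def test_signature_invariant_to_whole_molecule_reflection(ancestral):
    assert canonicalize(reflect(ancestral)).key == canonicalize(ancestral).key


def test_missing_gene_changes_signature_but_projection_matches(ancestral):
    partial = GeneOrder(
        "p", tuple(e for e in ancestral.elements if e[0] != "rrnS")
    )
    full_sig = canonicalize(ancestral)
    part_sig = canonicalize(partial)
    assert part_sig.key != full_sig.key
    assert part_sig.missing == ("rrnS",)
    projected = ancestral.restricted_to(partial.genes)
    assert canonicalize(projected).key == part_sig.key


# --- breakpoint distance -----------------------------------------------------

def test_breakpoint_identity(ancestral):
    assert breakpoint_distance(ancestral, ancestral) == 0


def test_breakpoint_single_transposition_five_gene_circle():
    a = GeneOrder("a", tuple((g, 1) for g in ("cox1", "cox2", "cox3", "cob", "nad1")))
    b = GeneOrder("b", tuple((g, 1) for g in ("cox1", "cox3", "cob", "cox2", "nad1")))
    assert breakpoint_distance(a, b) == 3
    assert breakpoint_distance(b, a) == 3


def test_breakpoint_requires_shared_genes(ancestral):
    lonely = GeneOrder("x", (("cox1", 1),))
    with pytest.raises(ValueError):
        breakpoint_distance(ancestral, lonely)


# --- event inference ---------------------------------------------------------

def test_identity_has_no_events(ancestral):
    assert infer_events(ancestral) == []


def test_wcy_shuffle_detected(ancestral):
    observed = apply_events(
        ancestral, [("swap_adjacent", "trnC", "trnY")], "g"
    )
    events = infer_events(observed)
    assert len(events) == 1
    assert events[0].kind == "shuffle"
    assert set(events[0].genes) <= {"trnC", "trnY"}


def test_r1_double_shuffle_two_events(ancestral):
    events = infer_events(apply_events(ancestral, R1_EVENTS, "g"))
    assert [e.kind for e in events] == ["shuffle", "shuffle"]


def test_trnl2_transposition_named_with_acceptor_cluster(ancestral):
    observed = apply_events(
        ancestral, R1_EVENTS + TRNL2_TRANSPOSITION, "g"
    )
    events = [e for e in infer_events(observed) if "trnL2" in e.genes]
    assert len(events) == 1
    assert events[0].kind == "transposition"
    assert set(events[0].acceptor_context) & {"trnM", "trnI", "trnQ"}


def test_replay_soundness_on_random_event_stacks(ancestral):
    """infer_events must replay onto the reference for arbitrary inputs
    (the check is built into infer_events and raises on failure)."""
    rng = np.random.default_rng(101)
    checked = 0
    for _ in range(500):
        try:
            observed = apply_events(
                ancestral, _random_events(rng, int(rng.integers(1, 5))), "g"
            )
        except ValueError:
            continue
        events = infer_events(observed)
        bp = breakpoint_distance(observed, ancestral)
        assert len(events) >= math.ceil(bp / 3)
        checked += 1
    assert checked > 400


def test_single_transposition_recovered_in_most_seeded_runs(ancestral):
    from conftest import remote_targets

    trnas = [g for g, _ in ancestral.elements if g.startswith("trn")]
    names = [g for g, _ in ancestral.elements]
    hits = runs = 0
    rng = np.random.default_rng(55)
    for _ in range(200):
        gene = str(rng.choice(trnas))
        target = str(rng.choice(remote_targets(gene, names)))
        observed = apply_events(ancestral, [("move", (gene,), target)], "g")
        events = infer_events(observed)
        runs += 1
        if (
            len(events) == 1
            and events[0].kind == "transposition"
            and events[0].genes == (gene,)
        ):
            hits += 1
    assert hits / runs >= 0.95


# --- typing ------------------------------------------------------------------

def test_identical_orders_form_one_type(ancestral):
    orders = [GeneOrder(f"g{i}", ancestral.elements) for i in range(10)]
    catalog = classify_types(orders)
    assert catalog.n_types == 1
    assert len(catalog.types[0].members) == 10


def test_r1_signature_always_labelled_r1(ancestral):
    shuffled = GeneOrder("wasp1", r1_order().elements)
    catalog = classify_types([ancestral, shuffled])
    assert catalog.n_types == 2
    assert catalog.label_of("wasp1") == "R1"
    assert catalog.label_of(ancestral.genome_id) == "R2"


def test_planted_types_recovered_with_perfect_membership():
    config = SimulationConfig(n_genomes=104, seed=21)
    orders, truth = simulate_gene_orders(config, n_types=38)
    catalog = classify_types(orders)
    assert catalog.n_types == 38
    for t in catalog.types:
        planted = {truth.type_of_genome[m] for m in t.members}
        assert len(planted) == 1  # members never mix planted types


def test_partial_order_joins_unique_complete_type(ancestral):
    partial = GeneOrder(
        "part", tuple(e for e in ancestral.elements if e[0] != "rrnS")
    )
    catalog = classify_types([ancestral, partial])
    assert catalog.n_types == 1
    assert set(catalog.types[0].members) == {ancestral.genome_id, "part"}


def test_ambiguous_partial_kept_separate(ancestral):
    # two complete types that differ only in rrnS placement: a partial
    # lacking rrnS matches both and must stay its own flagged type
    moved = apply_events(ancestral, [("move", ("rrnS",), "cox2")], "m")
    partial = GeneOrder(
        "part", tuple(e for e in ancestral.elements if e[0] != "rrnS")
    )
    catalog = classify_types([ancestral, moved, partial])
    assert catalog.n_types == 3
    flagged = next(t for t in catalog.types if "part" in t.members)
    assert flagged.ambiguous


def test_determinism_of_labels_and_events(ancestral):
    orders, _ = simulate_gene_orders(SimulationConfig(n_genomes=30, seed=3), 5)
    a = classify_types(orders).to_frame()
    b = classify_types(orders).to_frame()
    assert a.equals(b)


# --- tree mapping ------------------------------------------------------------

def balanced_tree(labels):
    taxa = list(labels)
    newick = f"(({','.join(taxa[:len(taxa)//2])}),({','.join(taxa[len(taxa)//2:])}));"
    return dendropy.Tree.get(data=newick, schema="newick")


def test_feature_confined_to_clade_is_synapomorphy(ancestral):
    carriers = [f"g{i}" for i in range(4)]
    others = [f"g{i}" for i in range(4, 8)]
    orders = [
        apply_events(ancestral, TRNL2_TRANSPOSITION, gid) for gid in carriers
    ] + [GeneOrder(gid, ancestral.elements) for gid in others]
    tree = balanced_tree(carriers + others)
    catalog = classify_types(orders)
    report = map_types_on_tree(catalog, tree, orders)
    row = report[report.marker == "feature:trnL2_at_miq_cluster"].iloc[0]
    assert row.synapomorphy
    assert row.n_carriers == 4


def test_outside_carrier_breaks_synapomorphy(ancestral):
    carriers = ["g0", "g1", "g2", "g3", "g7"]  # g7 sits in the other clade
    all_ids = [f"g{i}" for i in range(8)]
    orders = [
        apply_events(ancestral, TRNL2_TRANSPOSITION, gid)
        if gid in carriers else GeneOrder(gid, ancestral.elements)
        for gid in all_ids
    ]
    tree = balanced_tree(all_ids)
    report = map_types_on_tree(classify_types(orders), tree, orders)
    row = report[report.marker == "feature:trnL2_at_miq_cluster"].iloc[0]
    assert not row.synapomorphy
    assert row.non_carriers_in_clade  # the clean tips are listed


def test_unknown_carrier_raises(ancestral):
    orders = [GeneOrder("inside", ancestral.elements),
              GeneOrder("stranger", r1_order().elements)]
    tree = dendropy.Tree.get(data="(inside,other);", schema="newick")
    with pytest.raises(ValueError, match="stranger"):
        map_types_on_tree(classify_types(orders), tree, orders)
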