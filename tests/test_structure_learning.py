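"""GS/IAMB blankets, symmetry handling, skeleton, orientation, full learner."""

import numpy as np
import pytest

from noisenet import (
    DSeparationOracle,
    MarkovBlanketSet,
    PDAG,
    blankets_to_skeleton,
    build_motif,
    check_symmetry,
    gs_markov_blanket,
    iamb_markov_blanket,
    learn_blankets,
    learn_structure,
    orient_v_structures,
    propagate_orientations,
    simulate,
    symmetry_correct,
)
from noisenet.motif_models import MOTIF_EDGES, LARGE_NOISE_VARIANCE, MotifKind

EXPECTED_CPDAG = {
    "common_effect": ({("x", "z"), ("y", "z")}, set()),
    "three_chain": (set(), {frozenset(("x", "y")), frozenset(("y", "z"))}),
    "ffl_type1": (
        set(),
        {frozenset(("x", "y")), frozenset(("x", "z")), frozenset(("y", "z"))},
    ),
}


@pytest.mark.parametrize("kind", list(EXPECTED_CPDAG))
@pytest.mark.parametrize("algorithm", ["gs", "iamb"])
def test_oracle_recovers_cpdag(kind, algorithm):
    """With d-separation answering the CI queries, the learners return the
    exact Markov-equivalence class of each motif."""
    oracle = DSeparationOracle(["x", "y", "z"], MOTIF_EDGES[MotifKind(kind)])
    pdag = learn_structure(oracle, algorithm=algorithm)
    directed, undirected = EXPECTED_CPDAG[kind]
    assert pdag.directed_arcs == directed
    assert pdag.undirected_edges == undirected


def test_gs_blankets_on_faithful_data(faithful_datasets):
    ce = faithful_datasets["common_effect"]
    assert gs_markov_blanket(ce, "x") == {"y", "z"}  # child and co-parent
    chain = faithful_datasets["three_chain"]
    assert gs_markov_blanket(chain, "y") == {"x", "z"}
    assert gs_markov_blanket(chain, "x") == {"y"}


def test_gs_blankets_empty_under_large_effect_noise():
    """With very large effect-node noise all blankets are empty (up to the
    test's nominal false-positive rate, so we count over seeds)."""
    model = build_motif("common_effect", 2.0, (1.0, 1.0, np.sqrt(LARGE_NOISE_VARIANCE)))
    all_empty = 0
    for seed in range(10):
        data = simulate(model, 2000, seed=seed)
        all_empty += all(gs_markov_blanket(data, v) == set() for v in ("x", "y", "z"))
    assert all_empty >= 8


@pytest.mark.parametrize("kind", list(MotifKind))
def test_iamb_equals_gs_on_faithful_data(kind):
    """On faithful large-sample data the two blanket learners coincide."""
    model = build_motif(kind, 2.0, (1, 1, 1))
    for seed in range(5):
        data = simulate(model, 2000, seed=seed)
        for node in ("x", "y", "z"):
            assert iamb_markov_blanket(data, node) == gs_markov_blanket(data, node)


def test_iamb_deterministic(faithful_datasets):
    data = faithful_datasets["ffl_type1"]
    first = [iamb_markov_blanket(data, v) for v in ("x", "y", "z")]
    second = [iamb_markov_blanket(data, v) for v in ("x", "y", "z")]
    assert first == second


def test_check_symmetry_examples():
    sym = MarkovBlanketSet({"x": {"y"}, "y": {"x"}, "z": set()}, alpha=0.01)
    assert check_symmetry(sym) == []
    asym = MarkovBlanketSet({"x": set(), "y": set(), "z": {"x", "y"}}, alpha=0.01)
    assert check_symmetry(asym) == [("z", "x"), ("z", "y")]


def test_symmetry_correct_rules():
    asym = MarkovBlanketSet({"x": set(), "y": set(), "z": {"x", "y"}}, alpha=0.01)
    anded = symmetry_correct(asym, "AND")
    assert all(not s for s in anded.blankets.values())
    ored = symmetry_correct(asym, "OR")
    assert ored.blankets == {"x": {"z"}, "y": {"z"}, "z": {"x", "y"}}
    for rule in ("AND", "OR"):
        once = symmetry_correct(asym, rule)
        twice = symmetry_correct(once, rule)
        assert once.blankets == twice.blankets  # idempotent
        assert once.symmetric
    sym = MarkovBlanketSet({"x": {"y"}, "y": {"x"}, "z": set()}, alpha=0.01)
    for rule in ("AND", "OR"):
        assert symmetry_correct(sym, rule).blankets == sym.blankets


def test_or_correction_restores_common_effect_blankets():
    """The asymmetric blanket pattern of the large-noise-at-cause regime:
    adding the missing entries to Mb(x) restores the blankets characteristic
    of the common-effect motif."""
    asym = MarkovBlanketSet(
        {"x": set(), "y": {"x", "z"}, "z": {"x", "y"}}, alpha=0.01
    )
    assert check_symmetry(asym)
    ored = symmetry_correct(asym, "OR")
    assert ored.blankets == {"x": {"y", "z"}, "y": {"x", "z"}, "z": {"x", "y"}}


def test_large_noise_at_cause_breaks_blanket_symmetry():
    """Large noise at one cause of the common-effect motif produces at least
    one Markov-blanket symmetry violation in most replicates."""
    model = build_motif("common_effect", 2.0, (1.0, np.sqrt(LARGE_NOISE_VARIANCE), 1.0))
    hits = 0
    for seed in range(20):
        data = simulate(model, 2000, seed=seed)
        blankets = learn_blankets(data, "gs", 0.01)
        hits += bool(check_symmetry(blankets))
    assert hits > 10


def test_skeletons_and_separating_sets(faithful_datasets):
    for kind, (directed, undirected) in EXPECTED_CPDAG.items():
        data = faithful_datasets[kind]
        blankets = symmetry_correct(learn_blankets(data, "gs", 0.01), "AND")
        skel = blankets_to_skeleton(data, blankets, 0.01)
        expected_edges = {frozenset(e) for e in directed} | undirected
        assert skel.undirected_edges == expected_edges
    chain = faithful_datasets["three_chain"]
    blankets = symmetry_correct(learn_blankets(chain, "gs", 0.01), "AND")
    skel = blankets_to_skeleton(chain, blankets, 0.01)
    assert skel.separation_sets[frozenset(("x", "z"))] == frozenset(("y",))
    ce = faithful_datasets["common_effect"]
    blankets = symmetry_correct(learn_blankets(ce, "gs", 0.01), "AND")
    skel = blankets_to_skeleton(ce, blankets, 0.01)
    assert skel.separation_sets[frozenset(("x", "y"))] == frozenset()


def test_blankets_to_skeleton_requires_symmetry(faithful_datasets):
    asym = MarkovBlanketSet({"x": set(), "y": set(), "z": {"x", "y"}}, alpha=0.01)
    with pytest.raises(ValueError, match="symmetric"):
        blankets_to_skeleton(faithful_datasets["common_effect"], asym, 0.01)


def test_orient_v_structures():
    skel = PDAG(
        ["x", "y", "z"],
        undirected_edges={frozenset(("x", "z")), frozenset(("y", "z"))},
        separation_sets={frozenset(("x", "y")): frozenset()},
    )
    oriented = orient_v_structures(skel)
    assert oriented.directed_arcs == {("x", "z"), ("y", "z")}
    chain_skel = PDAG(
        ["x", "y", "z"],
        undirected_edges={frozenset(("x", "y")), frozenset(("y", "z"))},
        separation_sets={frozenset(("x", "z")): frozenset(("y",))},
    )
    assert orient_v_structures(chain_skel).directed_arcs == set()
    triangle = PDAG(
        ["x", "y", "z"],
        undirected_edges={frozenset(p) for p in (("x", "y"), ("x", "z"), ("y", "z"))},
    )
    assert orient_v_structures(triangle).directed_arcs == set()  # no unshielded triple


def test_propagation_rules():
    # R1: x->z, z-y, x and y non-adjacent  =>  z->y
    pdag = PDAG(["x", "y", "z"], {("x", "z")}, {frozenset(("y", "z"))})
    out = propagate_orientations(pdag)
    assert ("z", "y") in out.directed_arcs
    assert not out.undirected_edges
    # untouched triangle is a fixpoint
    triangle = PDAG(
        ["x", "y", "z"],
        undirected_edges={frozenset(p) for p in (("x", "y"), ("x", "z"), ("y", "z"))},
    )
    out = propagate_orientations(triangle)
    assert out == triangle
    # idempotence
    again = propagate_orientations(out)
    assert again == out


def test_meek_r2():
    # x->z->y with x-y  =>  x->y (avoids the cycle)
    pdag = PDAG(["x", "y", "z"], {("x", "z"), ("z", "y")}, {frozenset(("x", "y"))})
    out = propagate_orientations(pdag)
    assert ("x", "y") in out.directed_arcs


@pytest.mark.parametrize("kind", list(EXPECTED_CPDAG))
def test_learn_structure_faithful_regime(kind, faithful_datasets):
    pdag = learn_structure(faithful_datasets[kind], algorithm="gs", alpha=0.01)
    directed, undirected = EXPECTED_CPDAG[kind]
    assert pdag.directed_arcs == directed
    assert pdag.undirected_edges == undirected


def test_no_learned_pdag_contains_directed_cycle():
    for kind in MotifKind:
        for seed in range(5):
            data = simulate(build_motif(kind, 2.0, (1, 3, 0.5)), 500, seed=seed)
            pdag = learn_structure(data)
            assert not pdag.has_directed_cycle()


def test_large_noise_at_effect_mostly_empty_pdag():
    """Common-effect data with large noise at the effect node yields an empty
    graph in nearly all replicates."""
    model = build_motif("common_effect", 2.0, (1.0, 1.0, np.sqrt(LARGE_NOISE_VARIANCE)))
    empty = 0
    for seed in range(30):
        pdag = learn_structure(simulate(model, 2000, seed=seed))
        empty += not pdag.directed_arcs and not pdag.undirected_edges
    assert empty >= 27  # >= 90%


def test_pdag_validation():
    with pytest.raises(ValueError):
        PDAG(["a", "b"], {("a", "b")}, {frozenset(("a", "b"))})
    with pytest.raises(ValueError):
        PDAG(["a", "b", "c"], {("a", "b"), ("b", "c"), ("c", "a")})
    with pytest.raises(ValueError):
        PDAG(["a"], {("a", "a")})
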