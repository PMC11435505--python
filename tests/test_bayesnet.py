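"""Network structures, parameter learning and exact inference."""

import numpy as np
import pytest

from conftest import enumerate_posterior, random_network
from sensbn.bayesnet import (CPTSet, NetworkSpec, build_structure, infer,
                             latent_member_map, learn_parameters)


# ---------------------------------------------------------------------------
# Structures
# ---------------------------------------------------------------------------

def test_model_a_structure():
    spec = build_structure("A")
    assert spec.parents("KMAX") == ["CYSTEINE"]
    assert spec.parents("KDPRA_CLASS") == ["CYSTEINE"]
    assert spec.parents("DPRA_CYS") == ["CYSTEINE"]  # kDPRA wired like DPRACys
    assert "SKIN_DOCTOR" in spec.nodes and "TIMES" not in spec.nodes
    assert "INSILICO" not in spec.nodes


def test_model_b_structure():
    spec = build_structure("B")
    assert set(spec.children("INSILICO")) == {"SKIN_DOCTOR", "DEREK"}
    assert "INSILICO" in spec.latent
    assert "TIMES" not in spec.nodes


def test_baseline_structure():
    spec = build_structure("baseline")
    assert "TIMES" in spec.nodes
    for absent in ("KMAX", "KDPRA_CLASS", "INSILICO", "SKIN_DOCTOR", "DEREK"):
        assert absent not in spec.nodes


def test_kdpra_ablation_strips_nodes():
    spec = build_structure("A", include_kdpra=False)
    assert "KMAX" not in spec.nodes and "KDPRA_CLASS" not in spec.nodes
    assert "DPRA_CYS" in spec.nodes


def test_latent_member_map_groups():
    groups = latent_member_map(build_structure("B"))
    assert groups["CYTOX"] == ["KS_EC15", "KS_EC3", "KS_IC50"]
    assert set(groups["CYSTEINE"]) == {"DPRA_CYS", "DPRA_LYS", "KMAX",
                                       "KDPRA_CLASS"}
    assert set(groups["BIOAV"]) == {"LOG_KOW", "LOG_D", "WS",
                                    "PROTEIN_BINDING", "F_ION"}


def test_unknown_model_and_cycle_rejected():
    with pytest.raises(ValueError):
        build_structure("C")
    with pytest.raises(ValueError, match="cycle"):
        NetworkSpec(nodes={"a": 2, "b": 2}, edges=[("a", "b"), ("b", "a")],
                    target="a")


# ---------------------------------------------------------------------------
# Parameter learning
# ---------------------------------------------------------------------------

def _single_node_spec(card=2):
    return NetworkSpec(nodes={"x": card}, edges=[], target="x")


def test_learn_single_binary_node_k2():
    cpts = learn_parameters(_single_node_spec(), {"x": np.array([0, 0, 1])},
                            pseudo_count=1.0)
    assert cpts.tables["x"] == pytest.approx([3 / 5, 2 / 5])


def test_learn_no_data_gives_uniform():
    cpts = learn_parameters(_single_node_spec(card=4), {}, pseudo_count=1.0)
    assert cpts.tables["x"] == pytest.approx([0.25] * 4)


def test_available_case_counting_per_family():
    """A row missing a parent is dropped for that family, kept for others."""
    spec = NetworkSpec(nodes={"p": 2, "c": 2, "o": 2},
                       edges=[("p", "c")], target="c")
    table = {"p": np.array([0, -1, 1]),
             "c": np.array([1, 1, 0]),
             "o": np.array([0, 1, 1])}
    cpts = learn_parameters(spec, table, pseudo_count=1.0)
    # family (p, c): only rows 0 and 2 count
    assert cpts.tables["c"][0] == pytest.approx([1 / 3, 2 / 3])
    assert cpts.tables["c"][1] == pytest.approx([2 / 3, 1 / 3])
    # family (o,): all three rows count
    assert cpts.tables["o"] == pytest.approx([2 / 5, 3 / 5])


def test_pseudo_count_to_zero_recovers_ml():
    data = {"x": np.array([0] * 30 + [1] * 10)}
    cpts = learn_parameters(_single_node_spec(), data, pseudo_count=1e-9)
    assert cpts.tables["x"] == pytest.approx([0.75, 0.25], abs=1e-9)


def test_unseen_parent_config_defaults_to_uniform():
    spec = NetworkSpec(nodes={"p": 2, "c": 3}, edges=[("p", "c")], target="c")
    table = {"p": np.zeros(5, dtype=int), "c": np.array([0, 0, 1, 2, 0])}
    cpts = learn_parameters(spec, table, pseudo_count=1.0)
    assert cpts.tables["c"][1] == pytest.approx([1 / 3] * 3)


# ---------------------------------------------------------------------------
# Exact inference
# ---------------------------------------------------------------------------

def test_inference_matches_enumeration_on_random_networks():
    """Variable elimination == brute-force joint sum on 100 random cases."""
    rng = np.random.default_rng(2024)
    for _ in range(100):
        spec, cpts = random_network(rng)
        nodes = list(spec.nodes)
        query = nodes[int(rng.integers(len(nodes)))]
        others = [n for n in nodes if n != query]
        k = int(rng.integers(0, len(others) + 1))
        evidence = {n: int(rng.integers(spec.nodes[n]))
                    for n in rng.choice(others, size=k, replace=False)}
        got = infer(spec, cpts, evidence, query=query)
        want = enumerate_posterior(spec, cpts, evidence, query)
        np.testing.assert_allclose(got, want, atol=1e-10)
        assert got.sum() == pytest.approx(1.0, abs=1e-12)


def test_empty_evidence_is_prior_marginal():
    spec = NetworkSpec(nodes={"a": 2, "b": 3}, edges=[("a", "b")], target="b")
    rng = np.random.default_rng(1)
    pa = rng.dirichlet(np.ones(2))
    pb = rng.dirichlet(np.ones(3), size=2)
    cpts = CPTSet(parents={"a": [], "b": ["a"]}, tables={"a": pa, "b": pb})
    got = infer(spec, cpts, {})
    np.testing.assert_allclose(got, pa @ pb, atol=1e-12)


def test_deterministic_chain_propagates():
    spec = NetworkSpec(nodes={"a": 3, "b": 3, "c": 3},
                       edges=[("a", "b"), ("b", "c")], target="c")
    eye = np.eye(3)
    cpts = CPTSet(parents={"a": [], "b": ["a"], "c": ["b"]},
                  tables={"a": np.full(3, 1 / 3), "b": eye, "c": eye})
    got = infer(spec, cpts, {"a": 2})
    np.testing.assert_allclose(got, [0, 0, 1], atol=1e-12)
    # adding evidence consistent with the one-hot posterior changes nothing
    got2 = infer(spec, cpts, {"a": 2, "b": 2})
    np.testing.assert_allclose(got2, got, atol=1e-12)


def test_evidence_validation():
    spec = NetworkSpec(nodes={"a": 2, "b": 2}, edges=[("a", "b")], target="b")
    cpts = CPTSet(parents={"a": [], "b": ["a"]},
                  tables={"a": np.array([0.5, 0.5]), "b": np.full((2, 2), 0.5)})
    with pytest.raises(ValueError, match="out of range"):
        infer(spec, cpts, {"a": 5})
    with pytest.raises(ValueError, match="unknown node"):
        infer(spec, cpts, {"zz": 0})
    with pytest.raises(ValueError, match="must not be in evidence"):
        infer(spec, cpts, {"b": 0}, query="b")
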