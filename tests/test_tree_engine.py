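"""Tree validation, branch estimation, fold-back vs path-enumeration oracle."""

import json
import math

import numpy as np
import pytest

from asthmacea.cohort_prep import StrategyGroup, filter_evaluable
from asthmacea.synthetic_cohort import default_generator_params, generate_cohort, GeneratorParams
from asthmacea.tree_engine import (
    Branch,
    EmptyCellError,
    TreeError,
    TreeNode,
    build_strategy_tree,
    enumerate_paths,
    estimate_branch_probability,
    fold_back,
)

from conftest import make_record


def terminal(cost, asthma, label="leaf"):
    return TreeNode("terminal", label, payoff=(cost, asthma))


# -- estimate_branch_probability ------------------------------------------


def test_ratio_estimate():
    assert estimate_branch_probability(3, 1) == 0.75


def test_empty_numerator():
    assert estimate_branch_probability(0, 10) == 0.0


def test_empty_cell_additive_smoothing_is_symmetric():
    assert estimate_branch_probability(0, 0, smoothing="additive") == 0.5


def test_empty_cell_strict_raises():
    with pytest.raises(EmptyCellError):
        estimate_branch_probability(0, 0, smoothing="strict")


def test_negative_counts_rejected():
    with pytest.raises(ValueError):
        estimate_branch_probability(-1, 2)


def test_unknown_policy_rejected():
    with pytest.raises(ValueError, match="policy"):
        estimate_branch_probability(1, 1, smoothing="wishful")


# -- fold_back / enumerate_paths ------------------------------------------


def test_fold_back_single_terminal():
    assert fold_back(terminal(10.0, False)) == (10.0, 1.0)


def test_fold_back_two_branch_mean():
    tree = TreeNode(
        "chance",
        "root",
        branches=[
            Branch("a", 0.5, terminal(0.0, False)),
            Branch("b", 0.5, terminal(100.0, True)),
        ],
    )
    assert fold_back(tree) == (50.0, 0.5)


def test_enumerate_single_terminal():
    assert enumerate_paths(terminal(5.0, True)) == [(1.0, 5.0, True)]


def test_enumerate_balanced_depth_two():
    def chance(label, left, right):
        return TreeNode(
            "chance",
            label,
            branches=[Branch("l", 0.5, left), Branch("r", 0.5, right)],
        )

    tree = chance(
        "root",
        chance("a", terminal(1.0, False), terminal(2.0, True)),
        chance("b", terminal(3.0, False), terminal(4.0, True)),
    )
    paths = enumerate_paths(tree)
    assert len(paths) == 4
    assert all(p == pytest.approx(0.25) for p, _, _ in paths)


def test_probability_sum_violation_names_node():
    tree = TreeNode(
        "chance",
        "broken",
        branches=[Branch("a", 0.6, terminal(0, False)), Branch("b", 0.6, terminal(1, True))],
    )
    with pytest.raises(TreeError, match="broken"):
        fold_back(tree)


def test_decision_node_cannot_fold():
    tree = TreeNode(
        "decision",
        "choose",
        branches=[Branch("a", None, terminal(0, False))],
    )
    with pytest.raises(TreeError, match="decision"):
        fold_back(tree)


def random_tree(rng, depth=0, max_depth=5):
    if depth >= max_depth or rng.random() < 0.3:
        return terminal(float(rng.uniform(0, 1000)), bool(rng.random() < 0.5))
    k = int(rng.integers(2, 4))
    raw = rng.dirichlet(np.ones(k))
    # renormalise exactly so the validator's 1e-12 sum check passes
    probs = raw / raw.sum()
    probs[-1] = 1.0 - probs[:-1].sum()
    return TreeNode(
        "chance",
        f"n{depth}",
        branches=[
            Branch(f"b{i}", float(probs[i]), random_tree(rng, depth + 1, max_depth))
            for i in range(k)
        ],
    )


def test_fold_back_equals_path_enumeration_on_random_trees():
    rng = np.random.default_rng(2024)
    for _ in range(200):
        tree = random_tree(rng)
        cost, p = fold_back(tree)
        paths = enumerate_paths(tree)
        assert sum(pr for pr, _, _ in paths) == pytest.approx(1.0, abs=1e-9)
        oracle_cost = sum(pr * c for pr, c, _ in paths)
        oracle_p = sum(pr for pr, _, asthma in paths if not asthma)
        assert cost == pytest.approx(oracle_cost, abs=1e-9)
        assert p == pytest.approx(oracle_p, abs=1e-9)
        # bounds
        costs = [c for _, c, _ in paths]
        assert min(costs) - 1e-9 <= cost <= max(costs) + 1e-9
        assert -1e-12 <= p <= 1 + 1e-12


def scale_costs(node, k):
    if node.kind == "terminal":
        c, a = node.payoff
        return terminal(c * k, a, node.label)
    return TreeNode(
        node.kind,
        node.label,
        branches=[Branch(b.label, b.probability, scale_costs(b.node, k)) for b in node.branches],
    )


def test_scaling_terminal_costs_scales_expected_cost_only():
    rng = np.random.default_rng(7)
    for _ in range(20):
        tree = random_tree(rng)
        cost, p = fold_back(tree)
        cost3, p3 = fold_back(scale_costs(tree, 3.0))
        assert cost3 == pytest.approx(3.0 * cost, rel=1e-12)
        assert p3 == p


# -- serialization ---------------------------------------------------------


def test_tree_json_round_trip():
    rng = np.random.default_rng(99)
    tree = random_tree(rng)
    restored = TreeNode.from_dict(json.loads(tree.to_json()))
    assert fold_back(restored) == fold_back(tree)
    assert restored.to_dict() == tree.to_dict()


# -- build_strategy_tree ---------------------------------------------------


def test_build_requires_records(price_table):
    with pytest.raises(TreeError, match="no records"):
        build_strategy_tree([], price_table)


def test_build_rejects_non_evaluable(price_table):
    rec = make_record(ics=False, symptomatic=True, reversibility=None)
    with pytest.raises(TreeError, match="evaluable"):
        build_strategy_tree([rec], price_table)


def test_degenerate_cohort_single_unit_path(price_table):
    records = [
        make_record(id=f"r{i}", ics=False, symptomatic=False, reversibility=False)
        for i in range(5)
    ]
    tree = build_strategy_tree(records, price_table, empty_cell_policy="collapse")
    paths = enumerate_paths(tree)
    assert [p for p, _, _ in paths] == [pytest.approx(1.0)]
    _, p_avoided = fold_back(tree)
    assert p_avoided == 1.0


def test_micro_fixture_hand_computed(price_table):
    # Two paths: asymptomatic/negative (gp costs 28, 84) and
    # symptomatic/untreated/positive (gp costs 56, 0).
    records = [
        make_record(id="a1", symptomatic=False, reversibility=False,
                    resource_use={"gp_visit": 1}),
        make_record(id="a2", symptomatic=False, reversibility=False,
                    resource_use={"gp_visit": 3}),
        make_record(id="s1", symptomatic=True, reversibility=True,
                    resource_use={"gp_visit": 2}),
        make_record(id="s2", symptomatic=True, reversibility=True),
    ]
    tree = build_strategy_tree(records, price_table, empty_cell_policy="collapse")
    cost, p_avoided = fold_back(tree)
    # P(symptomatic) = 0.5; symptomatic all untreated and positive (rev+)
    # with mean cost (56+0)/2 = 28; asymptomatic all negative with mean
    # cost (28+84)/2 = 56.
    assert p_avoided == pytest.approx(0.5)
    assert cost == pytest.approx(0.5 * 28.0 + 0.5 * 56.0)
    paths = sorted(enumerate_paths(tree), key=lambda t: t[1])
    assert [(pr, c, a) for pr, c, a in paths] == [
        (pytest.approx(0.5), pytest.approx(28.0), True),
        (pytest.approx(0.5), pytest.approx(56.0), False),
    ]


def test_branch_parameter_recovery_within_three_se(price_table):
    n = 10_000
    p_sym, p_ics = 0.4, 0.55
    params = default_generator_params(seed=77)
    groups = dict(params.groups)
    groups[StrategyGroup.NFH] = groups[StrategyGroup.NFH].model_copy(
        update=dict(
            n=n,
            p_symptomatic=p_sym,
            p_ics_given_symptomatic=p_ics,
            missing_symptomatic=0.0,
            missing_reversibility=0.0,
            missing_hyperreactivity=0.0,
        )
    )
    params = GeneratorParams(groups=groups, seed=77)
    records = [r for r in generate_cohort(params) if r.family_history == "NFH"]
    kept, _ = filter_evaluable(records)
    tree = build_strategy_tree(kept, price_table, strategy_label="nfh")

    sym_branch = next(b for b in tree.branches if b.label == "symptomatic")
    se = math.sqrt(p_sym * (1 - p_sym) / n)
    assert abs(sym_branch.probability - p_sym) <= 3 * se

    treated_branch = next(b for b in sym_branch.node.branches if b.label == "treated")
    n_sym = round(sym_branch.probability * n)
    se_ics = math.sqrt(p_ics * (1 - p_ics) / n_sym)
    assert abs(treated_branch.probability - p_ics) <= 3 * se_ics


def test_strict_policy_raises_on_empty_cell(price_table):
    # No symptomatic records: the pharmacotherapy node is an empty cell.
    records = [make_record(id=f"r{i}", symptomatic=False, reversibility=False) for i in range(3)]
    with pytest.raises(EmptyCellError):
        build_strategy_tree(records, price_table, empty_cell_policy="strict")


def test_additive_policy_keeps_structure_and_logs(price_table):
    records = [make_record(id=f"r{i}", symptomatic=False, reversibility=False) for i in range(3)]
    events = []
    tree = build_strategy_tree(
        records, price_table, empty_cell_policy="additive", empty_cell_log=events
    )
    assert events  # the symptomatic subtree cells were empty
    sym_branch = next(b for b in tree.branches if b.label == "symptomatic")
    assert sym_branch.probability == 0.0
    # smoothed but unreachable subtree still folds back cleanly
    cost, p = fold_back(tree)
    assert p == pytest.approx(1.0)


def test_collapse_policy_prunes_empty_branches(price_table):
    records = [make_record(id=f"r{i}", symptomatic=False, reversibility=False) for i in range(3)]
    tree = build_strategy_tree(records, price_table, empty_cell_policy="collapse")
    assert [b.label for b in tree.branches] == ["asymptomatic"]
    assert tree.branches[0].probability == pytest.approx(1.0)


def test_intervention_costs_only_for_prevention_groups(price_table):
    records = [
        make_record(id="r0", symptomatic=False, reversibility=False,
                    resource_use={"gp_visit": 1, "nurse_visit": 2}),
    ]
    with_interv = build_strategy_tree(
        records, price_table, include_intervention=True, empty_cell_policy="collapse"
    )
    without = build_strategy_tree(
        records, price_table, include_intervention=False, empty_cell_policy="collapse"
    )
    assert fold_back(with_interv)[0] == pytest.approx(28.0 + 70.0)
    assert fold_back(without)[0] == pytest.approx(28.0)


def test_ics_with_missing_symptoms_placed_on_treated_path(price_table):
    records = [
        make_record(id="t0", ics=True, symptomatic=None, reversibility=True,
                    hyperreactivity=True),
        make_record(id="u0", ics=False, symptomatic=True, reversibility=False,
                    hyperreactivity=False),
    ]
    tree = build_strategy_tree(records, price_table)
    sym_branch = next(b for b in tree.branches if b.label == "symptomatic")
    assert sym_branch.probability == pytest.approx(1.0)
    treated = next(b for b in sym_branch.node.branches if b.label == "treated")
    assert treated.probability == pytest.approx(0.5)
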