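"""Symbolic-regression engine: evaluation, protection, constant
optimization, Pareto front, selection and canonical rendering."""

import math

import numpy as np
import pytest

from uhsr.errors import ConfigError, EvaluationError
from uhsr.symreg import (
    ExpressionTree, FrontMember, ParetoFront, SENTINEL, SRConfig, call,
    const, fit, optimize_constants, parse, select, simplex_coefficients,
    term_coefficient, to_canonical_string, var,
)


def linear_tree(a, b):
    """a*x + b"""
    return ExpressionTree(call("add", call("mul", const(a), var("x")),
                               const(b)))


# ---------------------------------------------------------------------------
# Evaluation and the independent recursive oracle
# ---------------------------------------------------------------------------

def oracle_eval(node, row):
    """Scalar recursive-descent reference evaluator, independent of the
    engine's vectorized implementation (including its protection rules)."""
    if node.kind == "const":
        return node.value
    if node.kind == "var":
        return row[node.name]
    args = [oracle_eval(a, row) for a in node.args]
    op = node.op
    if op == "add":
        return args[0] + args[1]
    if op == "sub":
        return args[0] - args[1]
    if op == "mul":
        return args[0] * args[1]
    if op == "div":
        if abs(args[1]) < 1e-9:
            return SENTINEL
        return args[0] / args[1]
    if op == "exp":
        return math.exp(min(max(args[0], -700.0), 700.0))
    if op == "log":
        if args[0] < 1e-9:
            return SENTINEL
        return math.log(args[0])
    if op == "sigma":
        return 1.0 / (1.0 + math.exp(min(max(-args[0], -700.0), 700.0)))
    raise AssertionError(op)


def random_tree(rng, names, depth):
    if depth == 0 or rng.random() < 0.3:
        if rng.random() < 0.5:
            return const(rng.uniform(-3, 3))
        return var(names[rng.integers(len(names))])
    op = ["add", "sub", "mul", "div", "exp", "log"][rng.integers(6)]
    if op in ("exp", "log"):
        return call(op, random_tree(rng, names, depth - 1))
    return call(op, random_tree(rng, names, depth - 1),
                random_tree(rng, names, depth - 1))


def test_evaluator_matches_recursive_oracle_on_random_trees():
    rng = np.random.default_rng(42)
    names = ["x", "y", "z"]
    X = {n: rng.uniform(-4, 4, 25) for n in names}
    for _ in range(100):
        tree = ExpressionTree(random_tree(rng, names, 3))
        got = tree.evaluate(X)
        want = np.array([
            oracle_eval(tree.root, {n: X[n][i] for n in names})
            for i in range(25)])
        finite = np.isfinite(want)
        np.testing.assert_allclose(got[finite], want[finite],
                                   rtol=1e-9, atol=1e-9)


def test_constant_tree_broadcasts():
    tree = ExpressionTree(const(0.69))
    out = tree.evaluate({"x": np.arange(5.0)})
    np.testing.assert_array_equal(out, np.full(5, 0.69))


def test_protected_division_emits_finite_sentinel_and_flag():
    tree = ExpressionTree(call("div", const(1.0), var("x")))
    values, violated = tree.evaluate_flagged({"x": np.array([0.0, 2.0])})
    assert violated
    assert np.all(np.isfinite(values))
    assert values[0] == SENTINEL and values[1] == 0.5


def test_protected_log_flag():
    tree = ExpressionTree(call("log", var("x")))
    values, violated = tree.evaluate_flagged({"x": np.array([-1.0, 1.0])})
    assert violated and np.all(np.isfinite(values)) and values[1] == 0.0


def test_unbound_variable_named_in_error():
    tree = ExpressionTree(var("missing"))
    with pytest.raises(EvaluationError, match="missing"):
        tree.evaluate({"x": np.zeros(3)})


# ---------------------------------------------------------------------------
# Constant optimization
# ---------------------------------------------------------------------------

def test_optimize_constants_linear_least_squares():
    rng = np.random.default_rng(0)
    x = rng.uniform(-2, 2, 100)
    y = 2.0 * x + 1.0
    refined = optimize_constants(linear_tree(0.0, 0.0), {"x": x}, y)
    a, b = refined.constants()
    assert a == pytest.approx(2.0, abs=1e-6)
    assert b == pytest.approx(1.0, abs=1e-6)


def test_optimize_constants_never_increases_loss():
    rng = np.random.default_rng(1)
    x = rng.uniform(-2, 2, 60)
    y = np.sin(x)  # not representable: optimizer can only do its best
    for a0, b0 in [(-3, 3), (0, 0), (5, -5)]:
        start = linear_tree(a0, b0)
        out = optimize_constants(start, {"x": x}, y)
        loss0 = np.mean((start.evaluate({"x": x}) - y) ** 2)
        loss1 = np.mean((out.evaluate({"x": x}) - y) ** 2)
        assert loss1 <= loss0 + 1e-12


def test_optimize_constants_no_constants_is_identity():
    tree = ExpressionTree(var("x"))
    assert optimize_constants(tree, {"x": np.arange(10.0)},
                              np.arange(10.0)) is tree


def test_xi_structure_constants_recovered():
    # xi = 0.37*a - 0.35*b - a*b + 0.69 on a noiseless grid
    rng = np.random.default_rng(2)
    a = rng.uniform(-2, 2, 400)
    b = rng.uniform(-2, 2, 400)
    y = 0.37 * a - 0.35 * b - a * b + 0.69
    skeleton = ExpressionTree(
        call("add",
             call("add", call("mul", const(0.0), var("a")),
                  call("mul", const(0.0), var("b"))),
             call("add", call("mul", const(0.0),
                              call("mul", var("a"), var("b"))),
                  const(0.0))))
    refined = optimize_constants(skeleton, {"a": a, "b": b}, y)
    np.testing.assert_allclose(refined.constants(), [0.37, -0.35, -1.0, 0.69],
                               atol=0.01)


# ---------------------------------------------------------------------------
# Selection and front invariants
# ---------------------------------------------------------------------------

def _front(entries):
    return ParetoFront([FrontMember(c, l, linear_tree(c, l))
                        for c, l in entries])


def test_select_parsimony_rule():
    front = _front([(3, 0.100), (9, 0.095), (15, 0.094)])
    assert select(front, 0.10).constants()[0] == 3
    assert select(front, 0.0).constants()[0] == 15
    single = _front([(5, 0.5)])
    assert select(single, 0.01).constants()[0] == 5


def test_select_empty_front_errors():
    with pytest.raises(EvaluationError):
        select(ParetoFront([]), 0.01)


def test_fit_recovers_exact_linear_target():
    rng = np.random.default_rng(0)
    x = rng.uniform(-3, 3, 200)
    y = 2.0 * x + 1.0
    cfg = SRConfig(primitives=("add", "sub", "mul"), population_size=300,
                   generations=12, seed=0)
    front = fit({"x": x}, y, cfg)
    # Pareto dominance: strictly increasing complexity, strictly decreasing loss
    comps = [m.complexity for m in front]
    losses = [m.loss for m in front]
    assert comps == sorted(comps) and len(set(comps)) == len(comps)
    assert all(a > b for a, b in zip(losses, losses[1:]))
    sel = select(front, 0.01)
    assert term_coefficient(sel, {"x": 1}) == pytest.approx(2.0, abs=0.01)
    assert term_coefficient(sel, {}) == pytest.approx(1.0, abs=0.01)
    best = min(losses)
    assert best < 1e-6


def test_fit_deterministic_under_seed():
    rng = np.random.default_rng(5)
    x = rng.uniform(-2, 2, 80)
    y = x * x + 0.5
    cfg = SRConfig(primitives=("add", "sub", "mul"), population_size=120,
                   generations=6, seed=9)
    f1 = fit({"x": x}, y, cfg)
    f2 = fit({"x": x}, y, cfg)
    assert [(m.complexity, m.loss, to_canonical_string(m.tree)) for m in f1] \
        == [(m.complexity, m.loss, to_canonical_string(m.tree)) for m in f2]


def test_fit_constant_target_degenerate_front():
    front = fit({"x": np.arange(20.0)}, np.full(20, 3.5), SRConfig(seed=0))
    assert len(front) == 1
    member = front.members[0]
    assert member.loss == 0.0
    assert member.tree.constants() == [3.5]


def test_fit_rejects_bad_inputs():
    with pytest.raises(ConfigError):
        fit({"x": np.arange(5.0)}, np.arange(5.0), SRConfig(seed=0))
    with pytest.raises(ConfigError):
        SRConfig(primitives=())


# ---------------------------------------------------------------------------
# Canonical strings, parsing, coefficient gauges
# ---------------------------------------------------------------------------

def test_canonical_string_of_rf_fixture():
    tree = ExpressionTree(call("sigma", call(
        "add",
        call("add", call("mul", const(5.15), var("psi")),
             call("mul", const(5.15), var("xi"))),
        const(1.55))))
    assert to_canonical_string(tree) == "sigma(5.15*psi + 5.15*xi + 1.55)"


def test_commutative_reordering_renders_identically():
    t1 = call("add", call("mul", const(2.0), var("a")), var("b"))
    t2 = call("add", var("b"), call("mul", var("a"), const(2.0)))
    assert to_canonical_string(ExpressionTree(t1)) == \
        to_canonical_string(ExpressionTree(t2))


def test_constant_precision_rendering():
    tree = ExpressionTree(const(0.69))
    assert to_canonical_string(tree, precision=3) == "0.690"
    assert to_canonical_string(tree) == "0.69"


def test_parse_round_trips_through_evaluator():
    tree = parse("sigma(5.15*psi + 5.15*xi + 1.55)")
    X = {"psi": np.array([0.0, -0.5]), "xi": np.array([0.0, 0.2])}
    want = 1 / (1 + np.exp(-(5.15 * X["psi"] + 5.15 * X["xi"] + 1.55)))
    np.testing.assert_allclose(tree.evaluate(X), want, rtol=1e-9)


def test_simplex_gauge_absorbs_intercept():
    # c0 + c1*x1 on a simplex (x1 + x2 = 1) equals (c1+c0)*x1 + c0*x2
    tree = ExpressionTree(call("add", call("mul", const(2.0), var("x1")),
                               const(-1.0)))
    coefs = simplex_coefficients(tree, ["x1", "x2"])
    assert coefs["x1"] == pytest.approx(1.0)
    assert coefs["x2"] == pytest.approx(-1.0)
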