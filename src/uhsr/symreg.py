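"""Genetic-programming symbolic regression over expression trees.

Candidate formulas are binary trees of primitive functions (+, -, *,
protected /, exp, protected log, and the logistic link sigma for rendering)
over named variables and real constants.  A seeded population evolves by
tournament selection, subtree crossover and several mutation operators; the
best expression at each complexity (node count) is archived, its constants
refined by local least squares, and the archive pruned to a Pareto front of
strictly increasing complexity and strictly decreasing training loss.
Equation selection then takes the simplest front member whose loss is within
a relative parsimony tolerance of the front's best.

Protected operators never emit non-finite values: division by (near-)zero
and log of a non-positive argument produce a large-magnitude sentinel and
mark the candidate so it receives worst-case fitness.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import sympy
from scipy.optimize import least_squares

from .errors import ConfigError, EvaluationError, UnsupportedFormError

logger = logging.getLogger(__name__)

SENTINEL = 1e10
_DIV_EPS = 1e-9
_EXP_MAX = 700.0


# ---------------------------------------------------------------------------
# Expression trees
# ---------------------------------------------------------------------------

_ARITY = {"add": 2, "sub": 2, "mul": 2, "div": 2, "exp": 1, "log": 1,
          "sigma": 1}


class Node:
    """One tree node: a constant, a named variable, or a primitive call."""

    __slots__ = ("kind", "op", "args", "value", "name")

    def __init__(self, kind, op=None, args=(), value=None, name=None):
        self.kind = kind
        self.op = op
        self.args = tuple(args)
        self.value = value
        self.name = name

    def copy(self) -> "Node":
        if self.kind == "call":
            return Node("call", op=self.op, args=[a.copy() for a in self.args])
        return Node(self.kind, value=self.value, name=self.name)


def const(v: float) -> Node:
    return Node("const", value=float(v))


def var(name: str) -> Node:
    return Node("var", name=name)


def call(op: str, *args: Node) -> Node:
    if op not in _ARITY:
        raise ConfigError(f"unknown primitive {op!r}")
    if len(args) != _ARITY[op]:
        raise ConfigError(f"{op} takes {_ARITY[op]} argument(s), got {len(args)}")
    return Node("call", op=op, args=args)


class ExpressionTree:
    """Immutable-by-convention wrapper around a root node."""

    def __init__(self, root: Node):
        self.root = root

    # -- structure ----------------------------------------------------------

    @property
    def complexity(self) -> int:
        """Total node count (constants and variables count one each)."""
        def count(n: Node) -> int:
            return 1 + sum(count(a) for a in n.args)
        return count(self.root)

    def copy(self) -> "ExpressionTree":
        return ExpressionTree(self.root.copy())

    def nodes(self):
        """Yield (node, path) pairs in preorder; path is a child-index tuple."""
        stack = [(self.root, ())]
        while stack:
            n, path = stack.pop()
            yield n, path
            for i in range(len(n.args) - 1, -1, -1):
                stack.append((n.args[i], path + (i,)))

    def subtree(self, path) -> Node:
        n = self.root
        for i in path:
            n = n.args[i]
        return n

    def replaced(self, path, new: Node) -> "ExpressionTree":
        """A copy of the tree with the subtree at `path` replaced."""
        def rebuild(n: Node, p) -> Node:
            if not p:
                return new.copy()
            args = list(n.args)
            args[p[0]] = rebuild(args[p[0]], p[1:])
            return Node("call", op=n.op, args=args)
        if not path:
            return ExpressionTree(new.copy())
        return ExpressionTree(rebuild(self.root, tuple(path)))

    def variables(self) -> tuple[str, ...]:
        out = []
        for n, _ in self.nodes():
            if n.kind == "var" and n.name not in out:
                out.append(n.name)
        return tuple(sorted(out))

    def constants(self) -> list[float]:
        """Constant values in preorder."""
        return [n.value for n, _ in self.nodes() if n.kind == "const"]

    def with_constants(self, values: Sequence[float]) -> "ExpressionTree":
        values = list(values)
        tree = self.copy()
        it = iter(values)
        for n, _ in tree.nodes():
            if n.kind == "const":
                n.value = float(next(it))
        return tree

    # -- evaluation ---------------------------------------------------------

    def _eval(self, X: Mapping[str, np.ndarray], n_rows: int):
        violated = [False]

        def ev(node: Node) -> np.ndarray:
            if node.kind == "const":
                return np.full(n_rows, node.value)
            if node.kind == "var":
                try:
                    return np.asarray(X[node.name], dtype=float)
                except KeyError:
                    raise EvaluationError(
                        f"unbound variable {node.name!r}") from None
            a = ev(node.args[0])
            if node.op == "exp":
                return np.exp(np.clip(a, -_EXP_MAX, _EXP_MAX))
            if node.op == "log":
                bad = a < _DIV_EPS
                if bad.any():
                    violated[0] = True
                    out = np.log(np.where(bad, 1.0, a))
                    out[bad] = SENTINEL
                    return out
                return np.log(a)
            if node.op == "sigma":
                with np.errstate(over="ignore"):
                    return 1.0 / (1.0 + np.exp(np.clip(-a, -_EXP_MAX, _EXP_MAX)))
            b = ev(node.args[1])
            if node.op == "add":
                return a + b
            if node.op == "sub":
                return a - b
            if node.op == "mul":
                return a * b
            if node.op == "div":
                bad = np.abs(b) < _DIV_EPS
                if bad.any():
                    violated[0] = True
                    out = a / np.where(bad, 1.0, b)
                    out[bad] = SENTINEL
                    return out
                return a / b
            raise ConfigError(f"unknown primitive {node.op!r}")

        with np.errstate(over="ignore", invalid="ignore"):
            values = ev(self.root)
        if not np.all(np.isfinite(values)):
            violated[0] = True
            values = np.nan_to_num(values, nan=SENTINEL, posinf=SENTINEL,
                                   neginf=-SENTINEL)
        return values, violated[0]

    def evaluate(self, X) -> np.ndarray:
        """Vectorized evaluation; protected, always finite."""
        X, n_rows = _as_table(X)
        values, _ = self._eval(X, n_rows)
        return values

    def evaluate_flagged(self, X) -> tuple[np.ndarray, bool]:
        """Evaluation plus a flag marking protection violations."""
        X, n_rows = _as_table(X)
        return self._eval(X, n_rows)

    def __repr__(self):
        return f"ExpressionTree({to_canonical_string(self)})"


def _as_table(X) -> tuple[dict, int]:
    if hasattr(X, "columns"):  # DataFrame
        cols = list(X.columns)
        return {c: X[c].to_numpy(dtype=float) for c in cols}, len(X)
    X = dict(X)
    n = len(next(iter(X.values())))
    return {k: np.asarray(v, dtype=float) for k, v in X.items()}, n


# ---------------------------------------------------------------------------
# Canonical rendering and sympy bridge
# ---------------------------------------------------------------------------

def _fmt_const(v: float, precision: Optional[int]) -> str:
    if precision is None:
        return f"{v:g}"
    return f"{v:.{precision}f}"


def to_canonical_string(expr: Union[ExpressionTree, Node],
                        precision: Optional[int] = None) -> str:
    """Deterministic infix rendering; commutative chains are sorted so any
    reordering of the same tree renders identically."""
    root = expr.root if isinstance(expr, ExpressionTree) else expr

    def flatten(n: Node, op: str) -> list[Node]:
        if n.kind == "call" and n.op == op:
            return flatten(n.args[0], op) + flatten(n.args[1], op)
        return [n]

    def render(n: Node) -> tuple[str, int]:
        # precedence: 1 additive, 2 multiplicative, 3 atom/call
        if n.kind == "const":
            s = _fmt_const(n.value, precision)
            return s, (3 if n.value >= 0 else 1)
        if n.kind == "var":
            return n.name, 3
        if n.op in ("exp", "log", "sigma"):
            inner, _ = render(n.args[0])
            return f"{n.op}({inner})", 3
        if n.op == "add":
            terms = flatten(n, "add")
            parts = [wrap(t, 1) for t in terms]
            consts = sorted(p for t, p in zip(terms, parts)
                            if t.kind == "const")
            rest = sorted(p for t, p in zip(terms, parts) if t.kind != "const")
            return " + ".join(rest + consts), 1
        if n.op == "mul":
            factors = flatten(n, "mul")
            parts = [wrap(f, 2) for f in factors]
            consts = sorted(p for f, p in zip(factors, parts)
                            if f.kind == "const")
            rest = sorted(p for f, p in zip(factors, parts)
                          if f.kind != "const")
            return "*".join(consts + rest), 2
        if n.op == "sub":
            a = wrap(n.args[0], 1)
            b = wrap(n.args[1], 2)  # parenthesize additive right operands
            return f"{a} - {b}", 1
        if n.op == "div":
            a = wrap(n.args[0], 2)
            b = wrap(n.args[1], 3)
            return f"{a}/{b}", 2
        raise ConfigError(f"unknown primitive {n.op!r}")

    def wrap(n: Node, need: int) -> str:
        s, prec = render(n)
        return f"({s})" if prec < need else s

    return render(root)[0]


_SIGMA = sympy.Function("sigma")


def to_sympy(expr: Union[ExpressionTree, Node]):
    """Convert a tree to a sympy expression (sigma expanded to the logistic)."""
    root = expr.root if isinstance(expr, ExpressionTree) else expr

    def conv(n: Node):
        if n.kind == "const":
            return sympy.Float(n.value)
        if n.kind == "var":
            return sympy.Symbol(n.name)
        args = [conv(a) for a in n.args]
        return {
            "add": lambda a, b: a + b,
            "sub": lambda a, b: a - b,
            "mul": lambda a, b: a * b,
            "div": lambda a, b: a / b,
            "exp": sympy.exp,
            "log": sympy.log,
            "sigma": lambda a: 1 / (1 + sympy.exp(-a)),
        }[n.op](*args)

    return conv(root)


def from_sympy(s) -> ExpressionTree:
    """Convert a sympy expression into a tree (inverse of :func:`to_sympy`
    for the supported grammar)."""
    def conv(e) -> Node:
        if e.is_Symbol:
            return var(str(e))
        if e.is_Number:
            return const(float(e))
        if isinstance(e, sympy.Add):
            args = sorted(e.args, key=sympy.srepr)
            node = conv(args[0])
            for a in args[1:]:
                node = call("add", node, conv(a))
            return node
        if isinstance(e, sympy.Mul):
            num, den = [], []
            for a in sorted(e.args, key=sympy.srepr):
                if isinstance(a, sympy.Pow) and a.exp.is_Integer and a.exp < 0:
                    den.append(sympy.Pow(a.base, -a.exp))
                else:
                    num.append(a)
            node = conv(num[0]) if num else const(1.0)
            for a in num[1:]:
                node = call("mul", node, conv(a))
            for d in den:
                node = call("div", node, conv(d))
            return node
        if isinstance(e, sympy.Pow):
            if e.exp.is_Integer and e.exp > 0:
                node = conv(e.base)
                for _ in range(int(e.exp) - 1):
                    node = call("mul", node, conv(e.base))
                return node
            if e.exp.is_Integer and e.exp < 0:
                node = const(1.0)
                inner = conv(sympy.Pow(e.base, -e.exp))
                return call("div", node, inner)
            raise UnsupportedFormError(f"unsupported power {e}")
        if isinstance(e, sympy.exp):
            return call("exp", conv(e.args[0]))
        if isinstance(e, sympy.log):
            return call("log", conv(e.args[0]))
        if e.func == _SIGMA:
            return call("sigma", conv(e.args[0]))
        raise UnsupportedFormError(f"unsupported sympy node {e!r}")

    return ExpressionTree(conv(s))


def parse(text: str) -> ExpressionTree:
    """Parse an infix equation string in the canonical grammar."""
    s = sympy.sympify(text, locals={"sigma": _SIGMA}, evaluate=True)
    return from_sympy(s)


def term_coefficient(expr: Union[ExpressionTree, "sympy.Expr"],
                     monomial: Mapping[str, int]) -> float:
    """Coefficient of a pure monomial (e.g. {"alpha": 1} for the linear
    alpha term) in the expanded polynomial form of an expression.

    Raises UnsupportedFormError if the expression is not polynomial in its
    variables.
    """
    s = expr if isinstance(expr, sympy.Expr) else to_sympy(expr)
    s = sympy.expand(s)
    syms = sorted(s.free_symbols, key=str)
    for name in monomial:
        sym = sympy.Symbol(name)
        if sym not in syms:
            syms.append(sym)
    try:
        poly = sympy.Poly(s, *syms)
    except sympy.PolynomialError as exc:
        raise UnsupportedFormError(f"not polynomial: {exc}") from exc
    mono = sympy.prod(
        [sympy.Symbol(k) ** v for k, v in monomial.items()], start=sympy.Integer(1))
    return float(poly.coeff_monomial(mono))


def simplex_coefficients(expr: ExpressionTree,
                         var_names: Sequence[str]) -> dict:
    """Per-variable coefficients of an expression fitted over variables that
    sum to one (a composition simplex), in the zero-intercept gauge.

    Because the variables sum to one, an intercept c0 is indistinguishable
    from adding c0 to every coefficient; the zero-intercept gauge absorbs it
    uniformly, so each coefficient equals the expression's value at that
    variable's pure-component vertex.  For affine expressions the absorption
    is done algebraically; otherwise each coefficient is read by evaluating
    at the vertex (the pure-component probe).
    """
    s = sympy.expand(to_sympy(expr))
    syms = [sympy.Symbol(v) for v in var_names]
    try:
        poly = sympy.Poly(s, *syms)
        affine = poly.total_degree() <= 1
    except sympy.PolynomialError:
        affine = False
    if affine:
        intercept = float(poly.coeff_monomial(1))
        return {v: float(poly.coeff_monomial(sym)) + intercept
                for v, sym in zip(var_names, syms)}
    out = {}
    for v in var_names:
        table = {name: np.array([1.0 if name == v else 0.0])
                 for name in var_names}
        out[v] = float(expr.evaluate(table)[0])
    return out


def is_affine(expr: ExpressionTree) -> bool:
    """True if the expression is degree <= 1 in every variable jointly."""
    s = sympy.expand(to_sympy(expr))
    syms = sorted(s.free_symbols, key=str)
    if not syms:
        return True
    try:
        poly = sympy.Poly(s, *syms)
    except sympy.PolynomialError:
        return False
    return poly.total_degree() <= 1


# ---------------------------------------------------------------------------
# Configuration, front, selection
# ---------------------------------------------------------------------------

@dataclass
class SRConfig:
    """Genetic-programming search settings.

    The defaults (population 1000, 40 generations, tournament 10, mutation
    0.7 / crossover 0.3, max complexity 30, parsimony tolerance 0.01) are
    this engine's own; they are sized so that targets representable in the
    primitive set at complexity ~10-20 are reliably recovered at desk scale.
    """

    primitives: tuple = ("add", "sub", "mul", "div", "exp", "log")
    population_size: int = 1000
    generations: int = 40
    tournament_size: int = 10
    p_crossover: float = 0.3
    p_mutation: float = 0.7
    max_complexity: int = 30
    parsimony_delta: float = 0.01
    const_range: tuple = (-3.0, 3.0)
    init_depth: tuple = (1, 3)
    const_opt_nfev: int = 60
    const_opt_final_nfev: int = 400
    seed: int = 0

    def __post_init__(self):
        if not self.primitives:
            raise ConfigError("empty primitive set")
        unknown = [p for p in self.primitives if p not in _ARITY]
        if unknown:
            raise ConfigError(f"unknown primitive(s): {unknown}")
        for r in (self.p_crossover, self.p_mutation):
            if not 0.0 <= r <= 1.0:
                raise ConfigError(f"rate {r} outside [0, 1]")
        if self.parsimony_delta < 0:
            raise ConfigError("parsimony tolerance must be >= 0")
        if self.population_size <= 1 or self.generations < 1:
            raise ConfigError("population and generations must be positive")


@dataclass(frozen=True)
class FrontMember:
    complexity: int
    loss: float
    tree: ExpressionTree


@dataclass
class ParetoFront:
    """Non-dominated (complexity, loss) expressions, simplest first."""

    members: list[FrontMember] = field(default_factory=list)

    def __iter__(self):
        return iter(self.members)

    def __len__(self):
        return len(self.members)

    @property
    def best_loss(self) -> float:
        return min(m.loss for m in self.members)


def _prune_front(entries: dict[int, tuple[float, ExpressionTree]]) -> ParetoFront:
    members = []
    best = math.inf
    for c in sorted(entries):
        loss, tree = entries[c]
        if loss < best:
            members.append(FrontMember(c, loss, tree))
            best = loss
    return ParetoFront(members)


def select(front: ParetoFront, delta: Optional[float] = None) -> ExpressionTree:
    """Parsimony selection: the minimum-complexity front member whose loss is
    within `delta` (relative) of the front's best loss."""
    if not front.members:
        raise EvaluationError("empty Pareto front")
    if delta is None:
        delta = 0.01
    if delta < 0:
        raise ConfigError("parsimony tolerance must be >= 0")
    best = front.best_loss
    # absolute epsilon so exactly-representable targets whose losses differ
    # only in machine noise count as ties
    threshold = best * (1.0 + delta) + 1e-12
    qualifying = [m for m in front.members if m.loss <= threshold]
    qualifying.sort(key=lambda m: (m.complexity, m.loss))
    return qualifying[0].tree


# ---------------------------------------------------------------------------
# Constant optimization
# ---------------------------------------------------------------------------

def _loss(tree: ExpressionTree, X, n_rows: int, y: np.ndarray) -> float:
    values, violated = tree._eval(X, n_rows)
    if violated:
        return math.inf
    resid = values - y
    return float(np.mean(resid * resid))


def optimize_constants(expr: ExpressionTree, X, y,
                       max_nfev: int = 400) -> ExpressionTree:
    """Refine the tree's constants by local least squares.

    The returned tree's training loss never exceeds the input tree's; on
    optimizer failure the original constants are retained (logged).
    """
    table, n_rows = _as_table(X)
    y = np.asarray(y, dtype=float)
    c0 = expr.constants()
    if not c0:
        return expr
    base_loss = _loss(expr, table, n_rows, y)

    def residual(c):
        values, violated = expr.with_constants(c)._eval(table, n_rows)
        r = values - y
        if violated or not np.all(np.isfinite(r)):
            r = np.nan_to_num(r, nan=SENTINEL, posinf=SENTINEL,
                              neginf=-SENTINEL)
        return r

    try:
        result = least_squares(residual, np.asarray(c0, dtype=float),
                               method="lm" if n_rows >= len(c0) else "trf",
                               max_nfev=max_nfev)
        candidate = expr.with_constants(result.x)
        if _loss(candidate, table, n_rows, y) < base_loss:
            return candidate
    except Exception as exc:  # divergence: keep original constants
        logger.warning("constant optimization failed (%s); keeping original",
                       exc)
    return expr


# ---------------------------------------------------------------------------
# The GP engine
# ---------------------------------------------------------------------------

class GPEngine:
    """Built-in genetic-programming backend.

    Any object with the same `fit(X, y, config) -> ParetoFront` signature can
    stand in for it (pluggable backend seam).
    """

    def fit(self, X, y, config: SRConfig) -> ParetoFront:
        table, n_rows = _as_table(X)
        y = np.asarray(y, dtype=float)
        if n_rows < 10:
            raise ConfigError("need at least 10 samples")
        if len(y) != n_rows:
            raise ConfigError("X and y length mismatch")
        if np.any(~np.isfinite(y)) or any(np.any(~np.isfinite(v))
                                          for v in table.values()):
            raise ConfigError("missing or non-finite values in inputs")

        names = list(table.keys())
        rng = np.random.default_rng(config.seed)

        if np.ptp(y) == 0.0:
            tree = ExpressionTree(const(float(y[0])))
            return ParetoFront([FrontMember(1, 0.0, tree)])

        binary = [p for p in config.primitives if _ARITY[p] == 2]
        cache: dict[str, float] = {}
        archive: dict[int, tuple[float, ExpressionTree]] = {}
        optimized: set[str] = set()

        def loss_of(tree: ExpressionTree) -> float:
            key = to_canonical_string(tree, precision=None)
            if key not in cache:
                cache[key] = _loss(tree, table, n_rows, y)
            return cache[key]

        def random_const() -> Node:
            lo, hi = config.const_range
            return const(rng.uniform(lo, hi))

        def random_terminal() -> Node:
            if rng.random() < 0.7:
                return var(names[rng.integers(len(names))])
            return random_const()

        def random_tree(depth: int) -> Node:
            if depth <= 0 or rng.random() < 0.25:
                return random_terminal()
            op = config.primitives[rng.integers(len(config.primitives))]
            if _ARITY[op] == 1:
                return Node("call", op=op, args=[random_tree(depth - 1)])
            return Node("call", op=op,
                        args=[random_tree(depth - 1), random_tree(depth - 1)])

        def init_population() -> list[ExpressionTree]:
            pop = []
            for n in names:
                pop.append(ExpressionTree(var(n)))
                pop.append(ExpressionTree(call("mul", random_const(), var(n))))
            lo, hi = config.init_depth
            while len(pop) < config.population_size:
                pop.append(ExpressionTree(
                    random_tree(int(rng.integers(lo, hi + 1)))))
            return pop[:config.population_size]

        def random_path(tree: ExpressionTree):
            paths = [p for _, p in tree.nodes()]
            return paths[rng.integers(len(paths))]

        def crossover(a: ExpressionTree, b: ExpressionTree) -> ExpressionTree:
            for _ in range(4):
                donor = b.subtree(random_path(b))
                child = a.replaced(random_path(a), donor)
                if child.complexity <= config.max_complexity:
                    return child
            return a.copy()

        def mutate(a: ExpressionTree) -> ExpressionTree:
            kind = rng.integers(4)
            if kind == 0:  # subtree replacement
                child = a.replaced(random_path(a), random_tree(2))
            elif kind == 1:  # point mutation
                child = a.copy()
                nodes = [n for n, _ in child.nodes()]
                node = nodes[rng.integers(len(nodes))]
                if node.kind == "const":
                    node.value += rng.normal(0.0, 0.5)
                elif node.kind == "var":
                    node.name = names[rng.integers(len(names))]
                else:
                    pool = ([p for p in config.primitives
                             if _ARITY[p] == _ARITY[node.op]] or [node.op])
                    node.op = pool[rng.integers(len(pool))]
            elif kind == 2:  # hoist
                child = ExpressionTree(a.subtree(random_path(a)).copy())
            else:  # expand: t -> t (op) c*var, accumulates linear structure
                op = binary[rng.integers(len(binary))] if binary else None
                if op is None:
                    child = a.copy()
                else:
                    term = call("mul", random_const(),
                                var(names[rng.integers(len(names))]))
                    child = ExpressionTree(call(op, a.root.copy(), term))
            if child.complexity > config.max_complexity:
                return a.copy()
            return child

        def tournament(pop, losses) -> ExpressionTree:
            idx = rng.integers(len(pop), size=config.tournament_size)
            best = min(idx, key=lambda i: (losses[i], pop[i].complexity, i))
            return pop[best]

        def absorb(tree: ExpressionTree, loss: float):
            c = tree.complexity
            if c > config.max_complexity:
                return
            if not math.isfinite(loss):
                return
            if c not in archive or loss < archive[c][0]:
                archive[c] = (loss, tree)

        population = init_population()
        for gen in range(config.generations):
            losses = [loss_of(t) for t in population]
            for t, l in zip(population, losses):
                absorb(t, l)

            # best candidate of this generation at each complexity
            gen_best: dict[int, tuple[float, ExpressionTree]] = {}
            for t, l in zip(population, losses):
                c = t.complexity
                if math.isfinite(l) and (c not in gen_best or l < gen_best[c][0]):
                    gen_best[c] = (l, t)

            # refine constants: new archive entries, plus promising
            # population candidates whose structure has not been polished yet
            to_polish = []
            for c in sorted(archive):
                to_polish.append(archive[c])
            for c, (l, t) in gen_best.items():
                ref = archive.get(c)
                if ref is None or l <= ref[0] * 1e3:
                    to_polish.append((l, t))
            to_polish.sort(key=lambda e: e[0])
            budget = 16
            for l, tree in to_polish:
                if budget == 0:
                    break
                key = to_canonical_string(tree)
                if key in optimized or not tree.constants():
                    continue
                optimized.add(key)
                budget -= 1
                better = optimize_constants(tree, table, y,
                                            max_nfev=config.const_opt_nfev)
                absorb(better, loss_of(better))

            elites = [t for _, (_, t) in sorted(archive.items())]
            nxt = [t.copy() for t in elites[:max(2, config.population_size // 20)]]
            while len(nxt) < config.population_size:
                if rng.random() < config.p_crossover:
                    child = crossover(tournament(population, losses),
                                      tournament(population, losses))
                else:
                    child = mutate(tournament(population, losses))
                nxt.append(child)
            population = nxt

        # final polish of every archived candidate
        for c in sorted(archive):
            loss, tree = archive[c]
            if tree.constants():
                better = optimize_constants(tree, table, y,
                                            max_nfev=config.const_opt_final_nfev)
                absorb(better, loss_of(better))

        return _prune_front(archive)


def fit(X, y, config: Optional[SRConfig] = None,
        backend=None) -> ParetoFront:
    """Evolve a Pareto front of candidate expressions for y = f(X).

    X may be a DataFrame (column names become variable names) or a mapping
    of name -> array.  Deterministic under a fixed config.seed.
    """
    if config is None:
        config = SRConfig()
    engine = backend if backend is not None else GPEngine()
    return engine.fit(X, y, config)
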