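"""Multinomial processing-tree (MPT) model representation.

An MPT model explains the frequencies of categorical responses as the
outcome of sequences of latent cognitive events.  Each experimental
condition is a *tree*; each root-to-leaf path is a *branch* whose
probability is a product of parameters :math:`\\theta` and complements
:math:`1-\\theta`; the probability of an observable response *category*
is the sum of the probabilities of the branches terminating in it.

This module defines the model objects, the EQN model-file format used
throughout the MPT software ecosystem, parameter restrictions
(equality constraints and fixed values), and numerical diagnostics for
structural completeness and local identifiability.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "ParamSpec",
    "BranchTerm",
    "Branch",
    "Tree",
    "MPTModel",
    "Restriction",
    "Equate",
    "Fix",
    "FrequencyTable",
    "EqnParseError",
    "RestrictionError",
    "ExpansionMap",
    "StructuralReport",
    "IdentifiabilityReport",
    "parse_eqn",
    "write_eqn",
    "category_probabilities",
    "apply_restrictions",
    "structural_check",
    "identifiability_check",
]


# --------------------------------------------------------------------------
# Model objects
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ParamSpec:
    """A model parameter: a probability in the closed unit interval."""

    name: str
    description: str = ""


@dataclass(frozen=True)
class BranchTerm:
    """One factor of a branch product: ``theta`` or ``1 - theta``."""

    param: str
    complement: bool = False

    def __str__(self) -> str:
        return f"(1-{self.param})" if self.complement else self.param


@dataclass(frozen=True)
class Branch:
    """A root-to-leaf path: tree, terminal category, and its product terms.

    An empty term tuple denotes probability 1.
    """

    tree: str
    category: str
    terms: tuple[BranchTerm, ...] = ()

    def probability(self, params: Mapping[str, float]) -> float:
        p = 1.0
        for t in self.terms:
            v = params[t.param]
            p *= (1.0 - v) if t.complement else v
        return p


@dataclass(frozen=True)
class Tree:
    """One condition of the design with its ordered response categories."""

    name: str
    categories: tuple[str, ...]
    item_type: str = ""

    def __post_init__(self) -> None:
        if len(self.categories) < 2:
            raise ValueError(f"tree {self.name!r} needs >= 2 categories")
        if len(set(self.categories)) != len(self.categories):
            raise ValueError(f"tree {self.name!r} has duplicate categories")


class ModelError(ValueError):
    """Raised when a model violates its structural invariants."""


@dataclass(frozen=True)
class MPTModel:
    """A complete MPT model: parameters, trees, and branches.

    The model is validated on construction: every branch must refer to a
    declared tree, one of its categories, and declared parameters.
    Completeness (per-tree branch probabilities summing to one) is a
    property of the *equations*, checked numerically by
    :func:`structural_check` rather than at construction time.
    """

    params: tuple[ParamSpec, ...]
    trees: tuple[Tree, ...]
    branches: tuple[Branch, ...]
    name: str = ""
    #: parameters pinned to constants by a ``Fix`` restriction (not free)
    fixed: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "params", tuple(self.params))
        object.__setattr__(self, "trees", tuple(self.trees))
        object.__setattr__(self, "branches", tuple(self.branches))
        object.__setattr__(self, "fixed", dict(self.fixed))
        names = [p.name for p in self.params]
        if len(set(names)) != len(names):
            raise ModelError("duplicate parameter names")
        tree_names = [t.name for t in self.trees]
        if len(set(tree_names)) != len(tree_names):
            raise ModelError("duplicate tree names")
        by_tree = {t.name: t for t in self.trees}
        declared = set(names)
        for b in self.branches:
            if b.tree not in by_tree:
                raise ModelError(f"branch references unknown tree {b.tree!r}")
            if b.category not in by_tree[b.tree].categories:
                raise ModelError(
                    f"branch references unknown category {b.category!r} "
                    f"in tree {b.tree!r}"
                )
            for t in b.terms:
                if t.param not in declared:
                    raise ModelError(f"branch references unknown parameter {t.param!r}")
        for name, value in self.fixed.items():
            if name not in declared:
                raise ModelError(f"fixed value for unknown parameter {name!r}")
            if not 0.0 <= value <= 1.0:
                raise ModelError(f"fixed value for {name!r} outside [0, 1]")

    # -- introspection ----------------------------------------------------

    @property
    def param_names(self) -> tuple[str, ...]:
        return tuple(p.name for p in self.params)

    @property
    def free_params(self) -> tuple[str, ...]:
        """Parameters that are estimated (declared minus fixed)."""
        return tuple(p.name for p in self.params if p.name not in self.fixed)

    def tree(self, name: str) -> Tree:
        for t in self.trees:
            if t.name == name:
                return t
        raise KeyError(name)

    def branches_of(self, tree: str) -> list[Branch]:
        return [b for b in self.branches if b.tree == tree]

    @property
    def n_cells(self) -> int:
        return sum(len(t.categories) for t in self.trees)

    @property
    def data_df(self) -> int:
        """Independent data cells: sum over trees of (categories - 1)."""
        return sum(len(t.categories) - 1 for t in self.trees)


# --------------------------------------------------------------------------
# Restrictions
# --------------------------------------------------------------------------

class RestrictionError(ValueError):
    """Raised for restrictions that are contradictory or ill-formed."""


@dataclass(frozen=True)
class Equate:
    """Constrain two parameters to share a single value."""

    a: str
    b: str


@dataclass(frozen=True)
class Fix:
    """Pin a parameter to a constant in [0, 1]."""

    param: str
    value: float


Restriction = Equate | Fix


@dataclass(frozen=True)
class ExpansionMap:
    """Recovers full-space parameter values from reduced-space values.

    ``representative`` maps each full-space parameter to the reduced-space
    parameter that carries its value; ``constants`` lists parameters pinned
    by a ``Fix``.
    """

    representative: Mapping[str, str]
    constants: Mapping[str, float]

    def expand(self, reduced: Mapping[str, float]) -> dict[str, float]:
        out: dict[str, float] = {}
        for full, rep in self.representative.items():
            out[full] = reduced[rep]
        out.update(self.constants)
        return out


def apply_restrictions(
    model: MPTModel, restrictions: Iterable[Restriction]
) -> tuple[MPTModel, ExpansionMap]:
    """Apply equality and fixed-value restrictions to a model.

    Equality chains are resolved transitively with union-find; the
    representative of each chain is the member declared first in the
    model's parameter list.  A ``Fix`` anywhere in a chain pins the whole
    chain; two different constants on one chain are contradictory.

    Returns the reduced model (merged parameters renamed to their
    representative, fixed parameters recorded in ``model.fixed``) and an
    :class:`ExpansionMap` back to the full parameter space.  Category
    probabilities are unchanged under expansion.
    """
    declared = list(model.param_names)
    order = {n: i for i, n in enumerate(declared)}
    parent = {n: n for n in declared}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra == rb:
            return
        # keep the earliest-declared name as representative
        if order[ra] > order[rb]:
            ra, rb = rb, ra
        parent[rb] = ra

    fixes: dict[str, float] = {}
    for r in restrictions:
        if isinstance(r, Equate):
            for p in (r.a, r.b):
                if p not in parent:
                    raise RestrictionError(f"unknown parameter {p!r} in equate")
            union(r.a, r.b)
        elif isinstance(r, Fix):
            if r.param not in parent:
                raise RestrictionError(f"unknown parameter {r.param!r} in fix")
            if not 0.0 <= r.value <= 1.0:
                raise RestrictionError(f"fix value {r.value} outside [0, 1]")
            fixes.setdefault(r.param, r.value)
            if fixes[r.param] != r.value:
                raise RestrictionError(
                    f"contradictory fixes for {r.param!r}: "
                    f"{fixes[r.param]} vs {r.value}"
                )
        else:  # pragma: no cover - defensive
            raise RestrictionError(f"unknown restriction {r!r}")

    # propagate fixes along chains; detect contradictions between chains
    chain_fix: dict[str, float] = {}
    for p, v in fixes.items():
        rep = find(p)
        if rep in chain_fix and chain_fix[rep] != v:
            raise RestrictionError(
                f"contradictory fixes on equated parameters "
                f"({rep!r}: {chain_fix[rep]} vs {v})"
            )
        chain_fix[rep] = v

    representative = {n: find(n) for n in declared}
    constants = {n: chain_fix[representative[n]] for n in declared
                 if representative[n] in chain_fix}

    kept = [p for p in model.params
            if representative[p.name] == p.name and p.name not in chain_fix]
    fixed_kept = {rep: v for rep, v in chain_fix.items()}

    def rename(term: BranchTerm) -> BranchTerm:
        rep = representative[term.param]
        return term if rep == term.param else replace(term, param=rep)

    new_branches = tuple(
        replace(b, terms=tuple(rename(t) for t in b.terms)) for b in model.branches
    )
    reduced = MPTModel(
        params=tuple(kept) + tuple(
            ParamSpec(rep, f"fixed at {v}") for rep, v in fixed_kept.items()
        ),
        trees=model.trees,
        branches=new_branches,
        name=model.name,
        fixed=fixed_kept,
    )
    # full-space parameters that are fixed map to their constant, not a
    # reduced free parameter
    rep_map = {n: representative[n] for n in declared if n not in constants}
    return reduced, ExpansionMap(representative=rep_map, constants=constants)


# --------------------------------------------------------------------------
# Category probabilities
# --------------------------------------------------------------------------

def category_probabilities(
    model: MPTModel, params: Mapping[str, float]
) -> dict[str, dict[str, float]]:
    """Category probabilities per tree at a given parameter vector.

    ``params`` must provide a value in [0, 1] for every free parameter of
    the model; fixed parameters take their pinned value.
    """
    values = dict(model.fixed)
    for name in model.free_params:
        if name not in params:
            raise KeyError(f"missing value for parameter {name!r}")
        v = params[name]
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"parameter {name!r} = {v} outside [0, 1]")
        values[name] = v
    out: dict[str, dict[str, float]] = {
        t.name: {c: 0.0 for c in t.categories} for t in model.trees
    }
    for b in model.branches:
        out[b.tree][b.category] += b.probability(values)
    return out


# --------------------------------------------------------------------------
# Frequency tables
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FrequencyTable:
    """Nonnegative integer response counts per (tree, category) cell."""

    counts: Mapping[tuple[str, str], int]

    def __post_init__(self) -> None:
        clean: dict[tuple[str, str], int] = {}
        for key, n in dict(self.counts).items():
            tree, cat = key
            if n != int(n) or n < 0:
                raise ValueError(
                    f"count for ({tree!r}, {cat!r}) must be a nonnegative "
                    f"integer, got {n!r}"
                )
            clean[(str(tree), str(cat))] = int(n)
        object.__setattr__(self, "counts", clean)

    def __getitem__(self, key: tuple[str, str]) -> int:
        return self.counts.get(key, 0)

    @property
    def trees(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for tree, _ in self.counts:
            seen.setdefault(tree)
        return tuple(seen)

    def tree_total(self, tree: str) -> int:
        return sum(n for (t, _), n in self.counts.items() if t == tree)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def validate_against(self, model: MPTModel) -> None:
        """Check that every observed cell exists in the model and every
        fitted tree has a positive total."""
        cells = {(t.name, c) for t in model.trees for c in t.categories}
        for key in self.counts:
            if key not in cells:
                raise ModelError(f"data cell {key!r} not present in the model")
        for t in model.trees:
            if self.tree_total(t.name) <= 0:
                raise ModelError(f"tree {t.name!r} has no observations")


# --------------------------------------------------------------------------
# EQN model files
# --------------------------------------------------------------------------

class EqnParseError(ValueError):
    """Malformed EQN content, reported with its line number."""


_TOKEN = re.compile(r"\s*(\(|\)|\*|-|1|[A-Za-z_][A-Za-z0-9_.]*)")


def _parse_product(expr: str, lineno: int) -> tuple[BranchTerm, ...]:
    """Parse ``a*(1-b)*c`` into branch terms.  The bare constant ``1``
    denotes the empty product."""
    pos = 0
    tokens: list[str] = []
    while pos < len(expr):
        m = _TOKEN.match(expr, pos)
        if not m:
            raise EqnParseError(f"line {lineno}: cannot tokenize {expr[pos:]!r}")
        tokens.append(m.group(1))
        pos = m.end()

    terms: list[BranchTerm] = []
    i = 0

    def expect(tok: str) -> None:
        nonlocal i
        if i >= len(tokens) or tokens[i] != tok:
            got = tokens[i] if i < len(tokens) else "end of line"
            raise EqnParseError(f"line {lineno}: expected {tok!r}, got {got!r}")
        i += 1

    def term() -> None:
        nonlocal i
        if i >= len(tokens):
            raise EqnParseError(f"line {lineno}: unexpected end of product")
        tok = tokens[i]
        if tok == "(":
            i += 1
            expect("1")
            expect("-")
            if i >= len(tokens) or not re.fullmatch(r"[A-Za-z_][A-Za-z0-9_.]*", tokens[i]):
                raise EqnParseError(f"line {lineno}: expected parameter after '1-'")
            terms.append(BranchTerm(tokens[i], complement=True))
            i += 1
            expect(")")
        elif tok == "1":
            i += 1  # multiplicative identity: contributes no term
        elif re.fullmatch(r"[A-Za-z_][A-Za-z0-9_.]*", tok):
            terms.append(BranchTerm(tok))
            i += 1
        else:
            raise EqnParseError(f"line {lineno}: unexpected token {tok!r}")

    term()
    while i < len(tokens):
        expect("*")
        term()
    return tuple(terms)


def _label(token: str, prefix: str) -> str:
    """File-boundary index mapping: numeric labels become stable names."""
    return f"{prefix}{int(token)}" if token.isdigit() else token


def parse_eqn(text: str) -> MPTModel:
    """Parse an EQN-format model description.

    The first line is treated as a header (branch-count or comment) and
    ignored, as in common MPT tools.  Each subsequent non-blank line is
    ``<tree> <category> <product>``; numeric tree/category labels are
    mapped to the stable names ``tree<i>`` / ``cat<j>``.  Duplicate
    (tree, category) lines accumulate as distinct branches of the same
    category.
    """
    lines = text.splitlines()
    if not lines:
        raise EqnParseError("empty EQN content")
    content = [(i, ln) for i, ln in enumerate(lines[1:], start=2)
               if ln.strip() and not ln.lstrip().startswith("#")]
    if not content:
        raise EqnParseError("EQN content has no branch lines")

    tree_cats: dict[str, list[str]] = {}
    branches: list[Branch] = []
    param_order: dict[str, None] = {}
    for lineno, ln in content:
        parts = ln.split(None, 2)
        if len(parts) != 3:
            raise EqnParseError(
                f"line {lineno}: expected 'tree category product', got {ln!r}"
            )
        tree = _label(parts[0], "tree")
        cat = _label(parts[1], "cat")
        terms = _parse_product(parts[2].replace(" ", ""), lineno)
        cats = tree_cats.setdefault(tree, [])
        if cat not in cats:
            cats.append(cat)
        branches.append(Branch(tree=tree, category=cat, terms=terms))
        for t in terms:
            param_order.setdefault(t.param)

    return MPTModel(
        params=tuple(ParamSpec(p) for p in param_order),
        trees=tuple(Tree(name, tuple(cats)) for name, cats in tree_cats.items()),
        branches=tuple(branches),
    )


def write_eqn(model: MPTModel, header: str | None = None) -> str:
    """Serialize a model to EQN text.

    The header line records the number of branch lines.  Tree and category
    names are written verbatim, so ``parse_eqn(write_eqn(m))`` is
    structurally identical to ``m`` (trees/categories ordered by first
    appearance, which follows the model's branch order).
    """
    lines = [header if header is not None else str(len(model.branches))]
    for b in model.branches:
        product = "*".join(str(t) for t in b.terms) if b.terms else "1"
        lines.append(f"{b.tree} {b.category} {product}")
    return "\n".join(lines) + "\n"


# --------------------------------------------------------------------------
# Numerical diagnostics
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class StructuralReport:
    max_deviation: float
    failed_trees: tuple[str, ...]
    n_points: int
    seed: int

    @property
    def passed(self) -> bool:
        return not self.failed_trees


def structural_check(
    model: MPTModel, n_points: int = 100, seed: int = 0, tol: float = 1e-9
) -> StructuralReport:
    """Verify numerically that each tree's branch probabilities sum to 1.

    Evaluates the per-tree sums at ``n_points`` random interior parameter
    vectors and reports the maximal absolute deviation from one; a tree
    deviating beyond ``tol`` at any point is flagged as incomplete.
    """
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    rng = np.random.default_rng(seed)
    free = model.free_params
    max_dev = 0.0
    failed: dict[str, None] = {}
    for _ in range(n_points):
        theta = dict(zip(free, rng.uniform(0.05, 0.95, size=len(free))))
        probs = category_probabilities(model, theta)
        for tree, cats in probs.items():
            dev = abs(sum(cats.values()) - 1.0)
            max_dev = max(max_dev, dev)
            if dev > tol:
                failed.setdefault(tree)
    return StructuralReport(
        max_deviation=max_dev, failed_trees=tuple(failed),
        n_points=n_points, seed=seed,
    )


@dataclass(frozen=True)
class IdentifiabilityReport:
    max_rank: int
    n_free: int
    n_points: int
    seed: int

    @property
    def identified(self) -> bool:
        """Local identifiability: full Jacobian column rank at some point."""
        return self.max_rank == self.n_free


def identifiability_check(
    model: MPTModel, n_points: int = 10, seed: int = 0, step: float = 1e-6
) -> IdentifiabilityReport:
    """Local identifiability via the rank of the probability Jacobian.

    At ``n_points`` random interior parameter vectors, the Jacobian of the
    map (free parameters -> stacked category probabilities) is computed by
    central differences and its rank recorded.  A model whose maximal rank
    falls short of the free-parameter count is locally non-identifiable:
    distinct parameter vectors produce identical category probabilities.
    """
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    rng = np.random.default_rng(seed)
    free = list(model.free_params)
    k = len(free)

    def stacked(theta: np.ndarray) -> np.ndarray:
        probs = category_probabilities(model, dict(zip(free, theta)))
        return np.array(
            [probs[t.name][c] for t in model.trees for c in t.categories]
        )

    max_rank = 0
    for _ in range(n_points):
        theta = rng.uniform(0.2, 0.8, size=k)
        jac = np.empty((model.n_cells, k))
        for j in range(k):
            up, dn = theta.copy(), theta.copy()
            up[j] += step
            dn[j] -= step
            jac[:, j] = (stacked(up) - stacked(dn)) / (2 * step)
        max_rank = max(max_rank, int(np.linalg.matrix_rank(jac, tol=1e-7)))
    return IdentifiabilityReport(
        max_rank=max_rank, n_free=k, n_points=n_points, seed=seed
    )
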