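"""Node-local packing as 0-1 quadratic programs, linearized and solved exactly.

At each node of the sweep the items carried on one side must be packed
into the bins (edges) on the other side so that the filled bin loads
track the bin capacities (junction weights) as closely as possible in
the least-squares sense:

    min f = sum_i (c_i - sum_j w_j x_ij)^2
    s.t.  sum_i x_ij = 1         for every item j  (one bin per item)
          sum_j x_ij >= n_i      for every bin i   (n_i = 1, or the count
                                 the bin held on its previous visit)
          x_ij in {0, 1}

The quadratic objective is linearized by introducing one product
variable x_ijik per quadratic term x_ij * x_ik (j <= k within bin i)
with the standard linking constraints, giving an equivalent 0-1 ILP
with m*n*(n+3)/2 variables.  Instances are tiny (usually fewer than 27
variables), so the ILP is solved exactly; an exhaustive-enumeration
oracle over the quadratic objective provides an independent route.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import LinearConstraint, milp
from scipy.optimize import Bounds


class PackingFormulationError(ValueError):
    """Invalid or infeasible packing instance."""


@dataclass(frozen=True)
class PackingInstance:
    """Bins with capacities, items with sizes, optional per-bin minimum counts.

    ``min_counts is None`` is the first-visit variant (every bin must
    receive at least one item, requiring #items >= #bins); otherwise bin
    i must receive at least ``min_counts[i]`` items.
    """

    bin_capacities: tuple[float, ...]
    item_sizes: tuple[float, ...]
    min_counts: tuple[int, ...] | None = None

    @property
    def m(self) -> int:
        return len(self.bin_capacities)

    @property
    def n(self) -> int:
        return len(self.item_sizes)

    def lower_bounds(self) -> tuple[int, ...]:
        if self.min_counts is None:
            return (1,) * self.m
        return self.min_counts

    def objective(self, x: np.ndarray) -> float:
        """Quadratic objective of a binary assignment matrix (m x n)."""
        loads = x @ np.asarray(self.item_sizes, dtype=float)
        return float(np.sum((np.asarray(self.bin_capacities) - loads) ** 2))

    def to_json(self) -> str:
        return json.dumps(
            {
                "bin_capacities": list(self.bin_capacities),
                "item_sizes": list(self.item_sizes),
                "min_counts": None if self.min_counts is None else list(self.min_counts),
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "PackingInstance":
        d = json.loads(s)
        mc = d["min_counts"]
        return cls(
            tuple(d["bin_capacities"]),
            tuple(d["item_sizes"]),
            None if mc is None else tuple(int(c) for c in mc),
        )


@dataclass(frozen=True)
class Assignment:
    """Binary solution matrix x[i, j] = 1 iff item j is packed into bin i."""

    x: tuple[tuple[int, ...], ...]
    objective: float

    def bin_of(self, j: int) -> int:
        for i, row in enumerate(self.x):
            if row[j]:
                return i
        raise PackingFormulationError(f"item {j} unassigned")

    def matrix(self) -> np.ndarray:
        return np.array(self.x, dtype=int)


@dataclass(frozen=True)
class LinearizedILP:
    """The 0-1 ILP equivalent of a quadratic packing instance.

    Variables are ordered: all x_ij (i-major), then all pair variables
    y_ijk ~ x_ij * x_ik for j <= k within each bin i (i-major, then the
    (j, k) pairs in lexicographic order).  Diagonal pairs j == k are
    retained as variables so the variable count reproduces the closed
    form m*n*(n+3)/2, but their linking constraints force y_ijj == x_ij.
    """

    instance: PackingInstance
    c: tuple[float, ...]                 # linear objective coefficients
    constant: float                      # objective constant term
    pair_index: tuple[tuple[int, int, int], ...]  # (i, j, k) per pair var

    @property
    def n_vars(self) -> int:
        return self.instance.m * self.instance.n + len(self.pair_index)

    def x_var(self, i: int, j: int) -> int:
        return i * self.instance.n + j

    def y_var(self, p: int) -> int:
        return self.instance.m * self.instance.n + p


def formulate_eq1(
    bins: Sequence[float], items: Sequence[float]
) -> PackingInstance:
    """First-visit instance: every bin must receive at least one item."""
    if len(bins) < 1 or len(items) < 1:
        raise PackingFormulationError("need at least one bin and one item")
    if len(items) < len(bins):
        raise PackingFormulationError(
            f"{len(items)} items into {len(bins)} bins: fewer items than "
            "bins is the trap case; use the replacement formulation"
        )
    return PackingInstance(tuple(float(b) for b in bins), tuple(float(w) for w in items))


def formulate_eq2(
    bins: Sequence[float], items: Sequence[float], min_counts: Sequence[int]
) -> PackingInstance:
    """Re-visit / trap instance: bin i must receive at least min_counts[i] items."""
    if len(bins) < 1 or len(items) < 1:
        raise PackingFormulationError("need at least one bin and one item")
    if len(min_counts) != len(bins):
        raise PackingFormulationError("one minimum count per bin required")
    if any(c < 0 for c in min_counts):
        raise PackingFormulationError("minimum counts must be non-negative")
    if sum(min_counts) > len(items):
        raise PackingFormulationError(
            f"infeasible: minimum counts sum to {sum(min_counts)} but only "
            f"{len(items)} items exist"
        )
    return PackingInstance(
        tuple(float(b) for b in bins),
        tuple(float(w) for w in items),
        tuple(int(c) for c in min_counts),
    )


def linearize(instance: PackingInstance) -> LinearizedILP:
    """Expand the squared loads into a linear objective over product variables.

    (c_i - sum_j w_j x_ij)^2 = c_i^2 - 2 c_i sum_j w_j x_ij
                               + sum_{j<=k} kappa_jk w_j w_k y_ijk
    with kappa = 1 on the diagonal (x^2 = x for binaries) and 2 off it.
    """
    m, n = instance.m, instance.n
    w = instance.item_sizes
    caps = instance.bin_capacities
    coeffs = [0.0] * (m * n)
    pair_index: list[tuple[int, int, int]] = []
    pair_coeffs: list[float] = []
    constant = 0.0
    for i in range(m):
        constant += caps[i] ** 2
        for j in range(n):
            coeffs[i * n + j] += -2.0 * caps[i] * w[j]
        for j in range(n):
            for k in range(j, n):
                kappa = 1.0 if j == k else 2.0
                pair_index.append((i, j, k))
                pair_coeffs.append(kappa * w[j] * w[k])
    return LinearizedILP(
        instance=instance,
        c=tuple(coeffs + pair_coeffs),
        constant=constant,
        pair_index=tuple(pair_index),
    )


def _solve_milp(ilp: LinearizedILP) -> Assignment:
    inst = ilp.instance
    m, n = inst.m, inst.n
    nv = ilp.n_vars
    rows_a: list[np.ndarray] = []
    lbs: list[float] = []
    ubs: list[float] = []

    def add_row(row: np.ndarray, lb: float, ub: float) -> None:
        rows_a.append(row)
        lbs.append(lb)
        ubs.append(ub)

    # each item in exactly one bin
    for j in range(n):
        row = np.zeros(nv)
        for i in range(m):
            row[ilp.x_var(i, j)] = 1.0
        add_row(row, 1.0, 1.0)
    # per-bin lower bounds
    for i, nmin in enumerate(inst.lower_bounds()):
        row = np.zeros(nv)
        for j in range(n):
            row[ilp.x_var(i, j)] = 1.0
        add_row(row, float(nmin), np.inf)
    # linking: y <= x_ij, y <= x_ik, x_ij + x_ik - 1 <= y
    for p, (i, j, k) in enumerate(ilp.pair_index):
        yv = ilp.y_var(p)
        row = np.zeros(nv)
        row[yv] = 1.0
        row[ilp.x_var(i, j)] = -1.0
        add_row(row, -np.inf, 0.0)
        if k != j:
            row = np.zeros(nv)
            row[yv] = 1.0
            row[ilp.x_var(i, k)] = -1.0
            add_row(row, -np.inf, 0.0)
        row = np.zeros(nv)
        row[ilp.x_var(i, j)] += 1.0
        row[ilp.x_var(i, k)] += 1.0
        row[yv] -= 1.0
        add_row(row, -np.inf, 1.0)

    con = LinearConstraint(np.vstack(rows_a), lbs, ubs)
    bounds = Bounds(0, 1)
    res = milp(
        c=np.asarray(ilp.c),
        integrality=np.ones(nv),
        bounds=bounds,
        constraints=[con],
    )
    if not res.success:
        raise PackingFormulationError(
            f"ILP reported infeasible/unsolved: {res.message} "
            f"(bins={inst.bin_capacities}, items={inst.item_sizes}, "
            f"min_counts={inst.lower_bounds()})"
        )
    xvals = np.rint(res.x[: m * n]).astype(int).reshape(m, n)
    x = tuple(tuple(int(v) for v in row) for row in xvals)
    return Assignment(x=x, objective=inst.objective(np.array(x)))


def _enumerate_assignments(instance: PackingInstance):
    """Yield (choice, matrix) over all item->bin maps meeting the bin minima."""
    m, n = instance.m, instance.n
    lows = instance.lower_bounds()
    for choice in itertools.product(range(m), repeat=n):
        counts = [0] * m
        for b in choice:
            counts[b] += 1
        if any(counts[i] < lows[i] for i in range(m)):
            continue
        x = np.zeros((m, n), dtype=int)
        for j, b in enumerate(choice):
            x[b, j] = 1
        yield choice, x


def brute_force_pack(instance: PackingInstance) -> Assignment:
    """Exhaustive-enumeration oracle over the quadratic objective.

    Ties among equal-objective optima are broken by the lexicographically
    smallest flattened assignment matrix -- the same rule solve_exact uses.
    """
    m, n = instance.m, instance.n
    if m ** n > 10 ** 6:
        raise PackingFormulationError(
            f"instance too large for enumeration: {m}^{n} assignments"
        )
    best: tuple[float, tuple, np.ndarray] | None = None
    for _, x in _enumerate_assignments(instance):
        obj = instance.objective(x)
        flat = tuple(int(v) for v in x.flatten())
        if best is None or obj < best[0] - 1e-12 or (
            abs(obj - best[0]) <= 1e-12 and flat < best[1]
        ):
            best = (obj, flat, x)
    if best is None:
        raise PackingFormulationError("no feasible assignment exists")
    x = best[2]
    return Assignment(
        x=tuple(tuple(int(v) for v in row) for row in x), objective=best[0]
    )


def _lex_refine(ilp: LinearizedILP, first: Assignment) -> Assignment:
    """Among all optima, pick the lexicographically smallest flattened x.

    Fixes x variables one at a time (row-major): try 0, keep it if the
    optimum is unchanged, else fix 1.  Only runs when ties are possible,
    i.e. always -- instances are tiny, each refinement solve is microscopic.
    """
    inst = ilp.instance
    m, n = inst.m, inst.n
    target = first.objective
    tol = 1e-9 * max(1.0, abs(target))
    fixed: dict[int, int] = {}
    for v in range(m * n):
        fixed[v] = 0
        try:
            cand = _solve_milp_fixed(ilp, fixed)
        except PackingFormulationError:
            cand = None
        if cand is not None and cand.objective <= target + tol:
            continue
        fixed[v] = 1
    final = _solve_milp_fixed(ilp, fixed)
    return final


def _solve_milp_fixed(ilp: LinearizedILP, fixed: dict[int, int]) -> Assignment:
    inst = ilp.instance
    m, n = inst.m, inst.n
    nv = ilp.n_vars
    lb = np.zeros(nv)
    ub = np.ones(nv)
    for v, val in fixed.items():
        lb[v] = ub[v] = val
    rows_a: list[np.ndarray] = []
    lbs: list[float] = []
    ubs: list[float] = []
    for j in range(n):
        row = np.zeros(nv)
        for i in range(m):
            row[ilp.x_var(i, j)] = 1.0
        rows_a.append(row); lbs.append(1.0); ubs.append(1.0)
    for i, nmin in enumerate(inst.lower_bounds()):
        row = np.zeros(nv)
        for j in range(n):
            row[ilp.x_var(i, j)] = 1.0
        rows_a.append(row); lbs.append(float(nmin)); ubs.append(np.inf)
    for p, (i, j, k) in enumerate(ilp.pair_index):
        yv = ilp.y_var(p)
        row = np.zeros(nv); row[yv] = 1.0; row[ilp.x_var(i, j)] = -1.0
        rows_a.append(row); lbs.append(-np.inf); ubs.append(0.0)
        if k != j:
            row = np.zeros(nv); row[yv] = 1.0; row[ilp.x_var(i, k)] = -1.0
            rows_a.append(row); lbs.append(-np.inf); ubs.append(0.0)
        row = np.zeros(nv)
        row[ilp.x_var(i, j)] += 1.0; row[ilp.x_var(i, k)] += 1.0; row[yv] -= 1.0
        rows_a.append(row); lbs.append(-np.inf); ubs.append(1.0)
    res = milp(
        c=np.asarray(ilp.c),
        integrality=np.ones(nv),
        bounds=Bounds(lb, ub),
        constraints=[LinearConstraint(np.vstack(rows_a), lbs, ubs)],
    )
    if not res.success:
        raise PackingFormulationError(f"ILP infeasible under fixing: {res.message}")
    xvals = np.rint(res.x[: m * n]).astype(int).reshape(m, n)
    x = tuple(tuple(int(v) for v in row) for row in xvals)
    return Assignment(x=x, objective=inst.objective(np.array(x)))


def solve_exact(instance: PackingInstance) -> Assignment:
    """Globally optimal assignment via the linearized 0-1 ILP.

    Fast paths: a single bin takes every item; a single item goes to the
    bin that must take it (or, with slack, the best-fitting bin) without
    building the ILP.  Ties among optima are broken lexicographically on
    the flattened assignment matrix.
    """
    m, n = instance.m, instance.n
    lows = instance.lower_bounds()
    if sum(lows) > n:
        raise PackingFormulationError(
            f"infeasible: minimum counts sum to {sum(lows)} > {n} items"
        )
    if m == 1:
        x = ((1,) * n,)
        return Assignment(x=x, objective=instance.objective(np.array(x)))
    if n == 1:
        # exactly one bin gets the item; min-count rows force it if any
        forced = [i for i in range(m) if lows[i] >= 1]
        if len(forced) > 1:
            raise PackingFormulationError("infeasible: several bins require the item")
        cands = forced if forced else list(range(m))
        w = instance.item_sizes[0]

        def cost(i: int) -> float:
            return sum(
                (c - (w if i == b else 0.0)) ** 2
                for b, c in enumerate(instance.bin_capacities)
            )

        best = min(cands, key=lambda i: (cost(i), i))
        x = tuple((1,) if i == best else (0,) for i in range(m))
        return Assignment(x=x, objective=instance.objective(np.array(x)))
    ilp = linearize(instance)
    first = _solve_milp(ilp)
    if m ** n <= 200_000:
        # cheap deterministic tie-break: enumerate feasible assignments and
        # keep the lexicographically smallest one matching the ILP optimum
        tol = 1e-9 * max(1.0, abs(first.objective))
        best_flat: tuple | None = None
        best_x = None
        for _, x in _enumerate_assignments(instance):
            if instance.objective(x) <= first.objective + tol:
                flat = tuple(int(v) for v in x.flatten())
                if best_flat is None or flat < best_flat:
                    best_flat, best_x = flat, x
        assert best_x is not None
        return Assignment(
            x=tuple(tuple(int(v) for v in row) for row in best_x),
            objective=instance.objective(best_x),
        )
    return _lex_refine(ilp, first)
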