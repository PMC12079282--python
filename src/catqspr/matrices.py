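"""N-tuple spatial (dis)similarity matrices and tensors.

The descriptor engine encodes a molecule's geometry as order-2 matrices and
order-3/4 tensors whose entries measure spatial relations among 2, 3 or 4
atoms.  Three processing stages are applied in a fixed order:

1. **metric** — a registered pairwise distance (Minkowski of any order p,
   Chebyshev, optionally Bhattacharyya); tuple entries of order 3/4 sum the
   metric over every pair inside the tuple,
2. **cutoff** — keep-all (KA), bond-path lag (LGP[k]) or geometric distance
   window (LGL[a-b] in angstroms); zeroed entries never re-enter,
3. **normalization** — none (NS), simple stochastic (SS, row/slice sums 1),
   double stochastic (DS, Sinkhorn), or mutual probability (MP, grand sum 1),
   followed by an optional matrix power (order 2 only).

The cutoff is applied *before* normalization so that stochastic rows
renormalize over surviving neighbours; every result records its provenance.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

from .errors import ConfigurationError, DomainError, ParameterizationError
from .structures import Molecule, covalent_radii

__all__ = [
    "BondGraph",
    "CutoffScheme",
    "TupleMatrix",
    "METRIC_REGISTRY",
    "register_metric",
    "resolve_metric",
    "bond_graph",
    "pair_matrix",
    "tuple_tensor",
    "normalize_matrix",
    "apply_cutoff",
]

NORMALIZATIONS = ("NS", "SS", "DS", "MP")
SINKHORN_MAX_ITER = 10_000


# ---------------------------------------------------------------------------
# Metric registry
# ---------------------------------------------------------------------------

def _minkowski(p: float) -> Callable[[np.ndarray], np.ndarray]:
    def dist(diff: np.ndarray) -> np.ndarray:
        return (np.abs(diff) ** p).sum(axis=-1) ** (1.0 / p)
    return dist


def _chebyshev(diff: np.ndarray) -> np.ndarray:
    return np.abs(diff).max(axis=-1)


#: token -> pairwise metric over coordinate differences (..., 3) -> (...).
#: Bhattacharyya is registered as a named slot but gated until an explicit
#: formula is supplied; no packaged descriptor needs it.
METRIC_REGISTRY: dict[str, Callable[[np.ndarray], np.ndarray] | None] = {
    "CH": _chebyshev,
    "BH": None,
}


def register_metric(token: str, fn: Callable[[np.ndarray], np.ndarray]) -> None:
    METRIC_REGISTRY[token] = fn


def resolve_metric(token: str) -> Callable[[np.ndarray], np.ndarray]:
    """Map a metric token to its pairwise function.

    ``M<k>`` tokens are Minkowski distances: k >= 10 is read as order k/10
    (M12 -> p=1.2, M15 -> p=1.5), smaller k as order k (M3 -> p=3).  Other
    tokens are looked up in :data:`METRIC_REGISTRY`.
    """
    if token.startswith("M") and token[1:].isdigit():
        k = int(token[1:])
        if k == 0:
            raise ConfigurationError("Minkowski order 0 is undefined")
        p = k / 10.0 if k >= 10 else float(k)
        return _minkowski(p)
    fn = METRIC_REGISTRY.get(token)
    if fn is None:
        known = sorted(t for t, f in METRIC_REGISTRY.items() if f is not None)
        raise ConfigurationError(
            f"metric token {token!r} not registered (or gated); registry: "
            f"M<k> (Minkowski), {known}")
    return fn


# ---------------------------------------------------------------------------
# Cutoff schemes and bond graph
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CutoffScheme:
    """KA (keep all), LGP (bond-path lag <= lag_max), LGL (distance window)."""

    kind: str
    lag_max: int | None = None
    window: tuple[float, float] | None = None

    def __post_init__(self):
        if self.kind not in ("KA", "LGP", "LGL"):
            raise ConfigurationError(f"unknown cutoff kind {self.kind!r}")
        if self.kind == "LGP" and (self.lag_max is None or self.lag_max < 1):
            raise ConfigurationError("LGP cutoff requires lag_max >= 1")
        if self.kind == "LGL":
            if self.window is None:
                raise ConfigurationError("LGL cutoff requires a window")
            a, b = self.window
            if not (0 < a < b):
                raise ConfigurationError(
                    f"LGL window must satisfy 0 < a < b, got {self.window}")

    def token(self) -> str:
        if self.kind == "KA":
            return "KA"
        if self.kind == "LGP":
            return f"LGP[{self.lag_max}]"
        a, b = self.window
        fmt = lambda x: f"{x:g}"
        return f"LGL[{fmt(a)}-{fmt(b)}]"


@dataclass(frozen=True)
class BondGraph:
    """Covalent adjacency and bond-count (lag) matrix of a molecule."""

    adjacency: np.ndarray
    lag: np.ndarray  # shortest path length in bonds; inf if disconnected

    @property
    def edges(self) -> list[tuple[int, int]]:
        i, j = np.nonzero(np.triu(self.adjacency, k=1))
        return list(zip(i.tolist(), j.tolist()))


def bond_graph(mol: Molecule, tolerance: float = 0.25) -> BondGraph:
    """Perceive bonds from covalent radii and derive the lag matrix.

    Atoms i, j are bonded iff their distance is at most
    ``(r_i + r_j) * (1 + tolerance)``; lags come from breadth-first search,
    with unreachable pairs flagged infinite.
    """
    radii = covalent_radii()
    missing = sorted({e for e in mol.elements if e not in radii})
    if missing:
        raise ParameterizationError(f"no covalent radius for elements {missing}")
    r = np.array([radii[e] for e in mol.elements])
    d = mol.distance_matrix()
    thresh = (r[:, None] + r[None, :]) * (1.0 + tolerance)
    adj = (d <= thresh) & ~np.eye(mol.n_atoms, dtype=bool)

    n = mol.n_atoms
    lag = np.full((n, n), np.inf)
    np.fill_diagonal(lag, 0.0)
    for src in range(n):
        seen = {src}
        queue = deque([(src, 0)])
        while queue:
            node, dist = queue.popleft()
            for nb in np.flatnonzero(adj[node]):
                if nb not in seen:
                    seen.add(nb)
                    lag[src, nb] = dist + 1
                    queue.append((nb, dist + 1))
    return BondGraph(adjacency=adj, lag=lag)


# ---------------------------------------------------------------------------
# TupleMatrix container
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TupleMatrix:
    """An order-2/3/4 spatial (dis)similarity array with provenance."""

    order: int
    entries: np.ndarray
    metric_id: str
    n_atoms: int
    normalization: str = "NS"
    power: int = 1
    cutoff: CutoffScheme = field(default_factory=lambda: CutoffScheme("KA"))

    def __post_init__(self):
        if self.order not in (2, 3, 4):
            raise ConfigurationError(f"tuple order must be 2, 3 or 4, "
                                     f"got {self.order}")
        if self.entries.shape != (self.n_atoms,) * self.order:
            raise ValueError("entries shape inconsistent with order/n_atoms")

    def to_csv(self, path) -> None:
        """Export for debugging; order-3/4 tensors are flattened row-major."""
        np.savetxt(path, self.entries.reshape(self.n_atoms, -1), delimiter=",")


def pair_matrix(mol: Molecule, metric_id: str) -> TupleMatrix:
    """Order-2 matrix of the registered metric over atom coordinates."""
    fn = resolve_metric(metric_id)
    xyz = mol.coords
    diff = xyz[:, None, :] - xyz[None, :, :]
    m = fn(diff)
    np.fill_diagonal(m, 0.0)
    return TupleMatrix(order=2, entries=m, metric_id=metric_id,
                       n_atoms=mol.n_atoms)


def tuple_tensor(mol: Molecule, order: int, metric_id: str) -> TupleMatrix:
    """Order-3/4 tensor: each distinct-index tuple sums the pairwise metric
    over its C(order, 2) internal pairs; tuples with repeated indices are 0.
    """
    if order not in (3, 4):
        raise ConfigurationError(f"tuple_tensor order must be 3 or 4, "
                                 f"got {order}")
    n = mol.n_atoms
    if n < order:
        raise DomainError(f"molecule has {n} atoms; need >= {order}")
    d = pair_matrix(mol, metric_id).entries
    if order == 3:
        t = d[:, :, None] + d[:, None, :] + d[None, :, :]
        t = _zero_repeated(t)
    else:
        t = (d[:, :, None, None] + d[:, None, :, None] + d[:, None, None, :]
             + d[None, :, :, None] + d[None, :, None, :] + d[None, None, :, :])
        t = _zero_repeated(t)
    return TupleMatrix(order=order, entries=t, metric_id=metric_id, n_atoms=n)


def _zero_repeated(t: np.ndarray) -> np.ndarray:
    """Zero every entry whose index tuple has a repeated index."""
    order = t.ndim
    n = t.shape[0]
    idx = np.indices(t.shape, sparse=True)
    mask = np.zeros(t.shape, dtype=bool)
    for a in range(order):
        for b in range(a + 1, order):
            mask |= idx[a] == idx[b]
    t = t.copy()
    t[mask] = 0.0
    return t


# ---------------------------------------------------------------------------
# Normalization and cutoffs
# ---------------------------------------------------------------------------

def normalize_matrix(M: TupleMatrix, scheme: str, power: int = 1,
                     tol: float = 1e-8, zero_rows: str = "error"
                     ) -> TupleMatrix:
    """Apply a stochastic normalization, then an optional matrix power.

    NS leaves entries unchanged; SS divides each row (each leading-index
    slice for tensors) by its sum; DS runs Sinkhorn row/column alternation
    to ``tol`` (order 2 only); MP divides by the grand sum.  The power is a
    true matrix power, defined for order 2 only (power 0 is the identity).
    ``zero_rows`` controls SS/DS rows that sum to zero: ``"error"`` raises,
    ``"keep"`` leaves them zero (used by the descriptor pipeline after
    aggressive cutoffs).
    """
    if scheme not in NORMALIZATIONS:
        raise ConfigurationError(
            f"unknown normalization {scheme!r}; valid: {NORMALIZATIONS}")
    if power < 0:
        raise ConfigurationError("matrix power must be >= 0")
    if power != 1 and M.order != 2:
        raise ConfigurationError("matrix powers are defined for order 2 only")
    e = M.entries
    if scheme in ("SS", "DS", "MP") and np.any(e < 0):
        raise DomainError(f"{scheme} normalization requires nonnegative entries")

    if scheme == "NS":
        out = e.copy()
    elif scheme == "SS":
        axes = tuple(range(1, M.order))
        sums = e.sum(axis=axes, keepdims=True)
        zero = sums == 0
        if np.any(zero) and zero_rows == "error":
            rows = np.flatnonzero(zero.reshape(M.n_atoms))
            raise DomainError(f"SS normalization: zero row(s)/slice(s) {rows}")
        safe = np.where(zero, 1.0, sums)
        out = e / safe
    elif scheme == "DS":
        if M.order != 2:
            raise NotImplementedError("DS (Sinkhorn) is defined for order 2")
        if np.any(e.sum(axis=1) == 0) or np.any(e.sum(axis=0) == 0):
            if zero_rows == "error":
                raise DomainError("DS normalization: zero row or column sum")
            out = e.copy()  # degenerate; leave untouched
        else:
            out = e.copy()
            for _ in range(SINKHORN_MAX_ITER):
                out = out / out.sum(axis=1, keepdims=True)
                out = out / out.sum(axis=0, keepdims=True)
                dev = max(np.abs(out.sum(axis=1) - 1).max(),
                          np.abs(out.sum(axis=0) - 1).max())
                if dev < tol:
                    break
            else:
                raise DomainError(
                    f"Sinkhorn failed to reach tol={tol} in "
                    f"{SINKHORN_MAX_ITER} alternations")
    else:  # MP
        total = e.sum()
        if total == 0:
            raise DomainError("MP normalization: grand sum is zero")
        out = e / total

    if M.order == 2 and power != 1:
        out = np.linalg.matrix_power(out, power)
    return replace(M, entries=out, normalization=scheme, power=power)


def apply_cutoff(M: TupleMatrix, scheme: CutoffScheme,
                 graph: BondGraph | None = None,
                 distances: np.ndarray | None = None) -> TupleMatrix:
    """Zero entries whose tuple contains a pair violating the cutoff.

    LGP needs a :class:`BondGraph`; LGL needs the geometric distance matrix
    (pairs outside ``[a, b]`` angstroms are excluded).  Applied before
    normalization so stochastic rows renormalize over survivors.
    """
    if scheme.kind == "KA":
        return replace(M, cutoff=scheme)
    if scheme.kind == "LGP":
        if graph is None:
            raise ConfigurationError("LGP cutoff requires a BondGraph")
        ok_pair = graph.lag <= scheme.lag_max
    else:
        if distances is None:
            raise ConfigurationError(
                "LGL cutoff requires the geometric distance matrix")
        a, b = scheme.window
        ok_pair = (distances >= a) & (distances <= b)
    np.fill_diagonal(ok_pair, True)

    n = M.n_atoms
    keep = np.ones(M.entries.shape, dtype=bool)
    idx = np.indices(M.entries.shape, sparse=True)
    for a_ in range(M.order):
        for b_ in range(a_ + 1, M.order):
            keep &= ok_pair[idx[a_], idx[b_]]
    out = np.where(keep, M.entries, 0.0)
    return replace(M, entries=out, cutoff=scheme)
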