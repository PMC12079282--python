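"""Applicability domain, descriptor-space projection and virtual screening.

Three complementary views decide whether a prediction can be trusted:

* **Williams plot** — leverage h against standardized residuals, with the
  conventional thresholds h* = 3(k+1)/n and |r| = 3;
* **NCA projection** — a supervised linear map to 2D maximizing stochastic
  nearest-neighbour classification of activity classes (response tertiles
  by default), used to visualize where a candidate falls;
* **LOF novelty** — the local outlier factor of a candidate relative to the
  training cloud in the projected space.

The packaged :class:`ReferenceModel` carries the published four-descriptor
regression for the initial rate of homogeneous quinoline hydrogenation and
converts descriptor values into r0 predictions in M s^-1.  A small
liquid-organic-hydrogen-carrier utility computes gravimetric H2 capacity.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError
from .regression import MLRResults
from .structures import load_property_tables

__all__ = [
    "WilliamsReport",
    "williams_report",
    "NcaResult",
    "nca_fit",
    "activity_bins",
    "lof_scores",
    "ReferenceModel",
    "REFERENCE_MODEL",
    "predict_r0",
    "ScreeningCandidate",
    "screen_candidates",
    "h2_capacity",
]


# ---------------------------------------------------------------------------
# Williams plot
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WilliamsReport:
    """Leverages and standardized residuals with outlier/influence flags."""

    leverage: np.ndarray
    std_resid: np.ndarray
    h_star: float
    resid_limit: float
    outlier: np.ndarray      # |standardized residual| > resid_limit
    influential: np.ndarray  # leverage > h_star
    query_leverage: np.ndarray | None = None
    query_influential: np.ndarray | None = None


def williams_report(fit: MLRResults, X_query=None,
                    resid_limit: float = 3.0) -> WilliamsReport:
    """Applicability-domain assessment via the Williams plot.

    Training leverages come from the hat diagonal (their sum is k+1);
    query leverages are ``x0' (X'X)^-1 x0`` with intercept-augmented rows.
    The leverage threshold is ``h* = 3 (k+1) / n``.
    """
    n, k = fit.model.nobs, fit.model.k
    h = fit.hat
    s = fit.s
    std_resid = fit.resid / (s * np.sqrt(1.0 - h))
    h_star = 3.0 * (k + 1) / n
    qh = qi = None
    if X_query is not None:
        Xq = np.asarray(X_query, dtype=float)
        if Xq.ndim == 1:
            Xq = Xq[None, :]
        if Xq.shape[1] != k:
            raise DomainError(
                f"query has {Xq.shape[1]} columns; model expects {k}")
        Xc = np.column_stack([np.ones(n), fit.model.X])
        xtx_inv = np.linalg.inv(Xc.T @ Xc)
        Q = np.column_stack([np.ones(len(Xq)), Xq])
        qh = np.einsum("ij,jk,ik->i", Q, xtx_inv, Q)
        qi = qh > h_star
    return WilliamsReport(
        leverage=h, std_resid=std_resid, h_star=h_star,
        resid_limit=resid_limit,
        outlier=np.abs(std_resid) > resid_limit,
        influential=h > h_star,
        query_leverage=qh, query_influential=qi)


# ---------------------------------------------------------------------------
# Neighbourhood components analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NcaResult:
    transform: np.ndarray       # (dim, n_features)
    objective_trace: np.ndarray  # objective after each accepted step
    accuracy_before: float      # 1-NN LOO accuracy in the raw space
    accuracy_after: float       # 1-NN LOO accuracy in the projected space

    def project(self, X) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.transform.T


def _knn_loo_accuracy(Z: np.ndarray, labels: np.ndarray) -> float:
    d = ((Z[:, None, :] - Z[None, :, :])**2).sum(-1)
    np.fill_diagonal(d, np.inf)
    nn = d.argmin(axis=1)
    return float((labels[nn] == labels).mean())


def nca_fit(X, labels, dim: int = 2, seed: int = 0, max_iter: int = 200,
            init: str = "identity", tol: float = 1e-8) -> NcaResult:
    """Neighbourhood components analysis by projected gradient ascent.

    Maximizes the stochastic-neighbour leave-one-out objective
    ``sum_i sum_{j in class(i)} p_ij`` with
    ``p_ij = softmax_j(-||A x_i - A x_j||^2)`` over ``dim x d`` linear maps
    A, using gradient ascent with a backtracking line search, so the
    objective is non-decreasing over accepted steps.  ``init="identity"``
    starts from the first ``dim`` rows of the identity (deterministic);
    ``init="random"`` uses the seed.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    n, d = X.shape
    if dim > d:
        raise DomainError(f"dim {dim} exceeds n_features {d}")
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise DomainError("NCA needs at least two classes")
    if np.any(counts < 2):
        small = classes[counts < 2]
        raise DomainError(f"singleton class(es) {small.tolist()}")
    same = labels[:, None] == labels[None, :]

    if init == "identity":
        A = np.eye(dim, d)
    else:
        A = np.random.default_rng(seed).standard_normal((dim, d)) * 0.1

    def objective_grad(A):
        Z = X @ A.T
        diff = Z[:, None, :] - Z[None, :, :]
        d2 = (diff**2).sum(-1)
        np.fill_diagonal(d2, np.inf)
        logits = -d2 + d2.min(axis=1, keepdims=True)  # stabilized
        P = np.exp(logits)
        P /= P.sum(axis=1, keepdims=True)
        p_i = (P * same).sum(axis=1)
        obj = float(p_i.sum())
        # gradient in the original-space outer products
        W = P * (p_i[:, None]) - P * same  # n x n weights (sign: ascent)
        Xdiff = X[:, None, :] - X[None, :, :]
        G = np.einsum("ij,ijk,ijl->kl", W, Xdiff, Xdiff)
        G = 2.0 * A @ (G + G.T) / 2.0
        return obj, G

    obj, G = objective_grad(A)
    trace = [obj]
    step = 1.0
    for _ in range(max_iter):
        improved = False
        s = step
        for _ in range(30):  # backtracking
            A_new = A + s * G
            obj_new, G_new = objective_grad(A_new)
            if obj_new > obj + 1e-14:
                A, obj, G = A_new, obj_new, G_new
                trace.append(obj)
                step = s * 1.1
                improved = True
                break
            s *= 0.5
        if not improved:
            break
        if len(trace) > 1 and trace[-1] - trace[-2] < tol:
            break

    acc0 = _knn_loo_accuracy(X, labels)
    acc1 = _knn_loo_accuracy(X @ A.T, labels)
    return NcaResult(transform=A, objective_trace=np.asarray(trace),
                     accuracy_before=acc0, accuracy_after=acc1)


def activity_bins(y, n_bins: int = 3) -> np.ndarray:
    """Quantile (tertile by default) class labels of a response vector."""
    y = np.asarray(y, dtype=float)
    if len(y) < n_bins:
        raise DomainError(f"need at least {n_bins} observations")
    if np.allclose(y, y[0]):
        raise DomainError("constant response yields a single class")
    edges = np.quantile(y, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.searchsorted(edges, y, side="left")


# ---------------------------------------------------------------------------
# Local outlier factor
# ---------------------------------------------------------------------------

def lof_scores(Z_train, Z_query=None, k_neighbors: int | None = None
               ) -> np.ndarray:
    """Classic local-outlier-factor scores (reachability-density ratios).

    Scores near 1 indicate density-consistent points, values well above 1
    outliers.  With ``Z_query=None`` each training point is scored against
    the others; query points are scored against the training cloud without
    joining it.  Delegates to scikit-learn's LocalOutlierFactor.
    """
    from sklearn.neighbors import LocalOutlierFactor
    Z_train = np.asarray(Z_train, dtype=float)
    n = len(Z_train)
    if k_neighbors is None:
        k_neighbors = min(10, n - 1)
    if not 0 < k_neighbors < n:
        raise DomainError(
            f"k_neighbors must lie in [1, n_train-1]={n - 1}, "
            f"got {k_neighbors}")
    if Z_query is None:
        lof = LocalOutlierFactor(n_neighbors=k_neighbors)
        lof.fit(Z_train)
        return -lof.negative_outlier_factor_
    lof = LocalOutlierFactor(n_neighbors=k_neighbors, novelty=True)
    lof.fit(Z_train)
    return -lof.score_samples(np.asarray(Z_query, dtype=float))


# ---------------------------------------------------------------------------
# Packaged reference model and screening
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReferenceModel:
    """The published four-descriptor regression for log10(r0 / M s^-1)."""

    intercept: float
    coefficients: tuple[float, ...]
    standard_errors: tuple[float, ...]  # intercept first
    descriptor_names: tuple[str, ...]
    response_sign: int = +1
    version: str = "1.0"

    def predict_log(self, D) -> np.ndarray:
        D = np.atleast_2d(np.asarray(D, dtype=float))
        if D.shape[1] != len(self.coefficients):
            raise DomainError(
                f"expected {len(self.coefficients)} descriptor values")
        if not np.all(np.isfinite(D)):
            raise DomainError("descriptor values must be finite")
        return self.intercept + D @ np.asarray(self.coefficients)


#: Final packaged model: intercept and the four descriptor coefficients
#: (softness lag-5 median; electronegativity-softness short-range geometric
#: mean; mass-hardness mid-range sum; mass variation coefficient).
REFERENCE_MODEL = ReferenceModel(
    intercept=-5.72,
    coefficients=(7.90, 1.72, -0.443, 0.161),
    standard_errors=(0.35, 0.97, 0.30, 0.071, 0.061),
    descriptor_names=(
        "I50_F_AB_nCi_2_M12_SS1_T_LGP[5]_s_MID",
        "GM_B_AB_nCi_2_M15_SS3_T_LGL[1-2]_e-s_MID",
        "S_B_AB_nCi_2_M3_SS4_T_LGL[2-3]_m-h_MID",
        "VC_Q_AB_nCi_2_M15_NS4_T_KA_m_MID",
    ),
)


def predict_r0(model: ReferenceModel, D) -> tuple[np.ndarray, np.ndarray]:
    """(log response, r0 in M s^-1) for descriptor rows ``D``.

    ``r0 = 10 ** (sign * log_response)`` per the model's response
    convention flag; predictions decompose additively in the descriptors.
    """
    log_resp = model.predict_log(D)
    r0 = 10.0 ** (model.response_sign * log_resp)
    return log_resp, r0


@dataclass(frozen=True)
class ScreeningCandidate:
    """One virtual-screening record with domain membership flags."""

    id: str
    descriptors: tuple[float, ...]
    log_response: float
    r0: float
    leverage: float
    in_domain: bool
    lof_score: float


def screen_candidates(fit: MLRResults, ids: Sequence[str], D,
                      model: ReferenceModel | None = None,
                      nca: NcaResult | None = None,
                      lof_threshold: float = 1.5,
                      k_neighbors: int | None = None
                      ) -> list[ScreeningCandidate]:
    """Predict r0 for candidate descriptor rows and flag domain membership.

    A candidate is in-domain when its leverage against the training design
    is below h* and (when an NCA projection is supplied) its LOF in the
    projected training cloud is below ``lof_threshold``.  Out-of-domain
    candidates are reported with flags rather than suppressed.
    """
    model = model or REFERENCE_MODEL
    D = np.atleast_2d(np.asarray(D, dtype=float))
    log_resp, r0 = predict_r0(model, D)
    rep = williams_report(fit, X_query=D)
    if nca is not None:
        Z_train = nca.project(fit.model.X)
        Z_query = nca.project(D)
        lof = lof_scores(Z_train, Z_query, k_neighbors=k_neighbors)
    else:
        lof = lof_scores(fit.model.X, D, k_neighbors=k_neighbors)
    out = []
    for i, cid in enumerate(ids):
        in_dom = (not rep.query_influential[i]) and lof[i] < lof_threshold
        out.append(ScreeningCandidate(
            id=str(cid), descriptors=tuple(D[i]),
            log_response=float(log_resp[i]), r0=float(r0[i]),
            leverage=float(rep.query_leverage[i]), in_domain=bool(in_dom),
            lof_score=float(lof[i])))
    return out


# ---------------------------------------------------------------------------
# LOHC gravimetric capacity
# ---------------------------------------------------------------------------

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def _parse_formula(formula: str | Mapping[str, int]) -> dict[str, int]:
    if isinstance(formula, Mapping):
        return dict(formula)
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_RE.finditer(formula):
        if m.start() != pos:
            raise DomainError(f"malformed formula {formula!r}")
        pos = m.end()
        counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
    if pos != len(formula) or not counts:
        raise DomainError(f"malformed formula {formula!r}")
    return counts


def h2_capacity(formula: str | Mapping[str, int], n_h2: int) -> float:
    """Gravimetric hydrogen capacity in %wt for a carrier taking n_h2 H2.

    ``100 * n_h2 M(H2) / (M(carrier) + n_h2 M(H2))`` with standard atomic
    masses; quinoline (C9H7N) with 5 H2 gives 7.2 %wt.
    """
    if n_h2 < 0:
        raise DomainError("n_h2 must be >= 0")
    masses = load_property_tables()["m"].values
    counts = _parse_formula(formula)
    unknown = sorted(set(counts) - set(masses))
    if unknown:
        raise DomainError(f"unknown element(s) in formula: {unknown}")
    m_carrier = sum(masses[e] * c for e, c in counts.items())
    m_h2 = n_h2 * 2 * masses["H"]
    return 100.0 * m_h2 / (m_carrier + m_h2)
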