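"""Multiple-linear-regression QSPR modelling and its validation battery.

The central object is :class:`QsprMLR`, a model built from a descriptor
matrix and a log-scale response, whose :meth:`~QsprMLR.fit` returns an
:class:`MLRResults` carrying coefficients with standard errors, goodness of
fit, residuals and the hat diagonal, plus the validation methods the QSPR
literature expects: leave-one-out Q² (via the PRESS identity), bootstrap
Q², Y-randomization (response scrambling), residual diagnostics
(Shapiro–Wilk, Durbin–Watson, VIF) and descriptor importance.  Genetic
subset selection and random train/test split robustness studies operate on
top of the same machinery.

The response convention is ``y = log10(r0 / (M s^-1))``; a sign flag allows
the reciprocal convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, SingularityError

__all__ = [
    "QsprMLR",
    "MLRResults",
    "DiagnosticsReport",
    "BootstrapResult",
    "YRandomizationResult",
    "RandomSplitSummary",
    "fit_mlr",
    "q2_loo",
    "bootstrap_q2",
    "y_randomization",
    "residual_diagnostics",
    "descriptor_importance",
    "ga_select",
    "random_split_study",
]

DEFAULT_SEED = 20250430


# ---------------------------------------------------------------------------
# fast OLS core (shared by every resampling loop)
# ---------------------------------------------------------------------------

def _design(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return np.column_stack([np.ones(len(X)), X])


def _qr_ols(Xc: np.ndarray, y: np.ndarray):
    """OLS via thin QR; returns (beta, resid, hat_diag)."""
    Q, R = np.linalg.qr(Xc)
    diag = np.abs(np.diag(R))
    if np.any(diag < 1e-10 * max(diag.max(), 1.0)):
        dep = np.flatnonzero(diag < 1e-10 * max(diag.max(), 1.0)) - 1
        raise SingularityError(
            f"design matrix is rank deficient; dependent column(s) "
            f"{[int(d) for d in dep]} (0-based, -1 = intercept)")
    beta = np.linalg.solve(R, Q.T @ y)
    resid = y - Xc @ beta
    hat = (Q**2).sum(axis=1)
    return beta, resid, hat


def _press_q2(resid: np.ndarray, hat: np.ndarray, sst: float) -> float:
    if np.any(hat >= 1.0 - 1e-12):
        raise DomainError("degenerate leverage (h_i = 1): PRESS undefined")
    press = float(((resid / (1.0 - hat)) ** 2).sum())
    return 1.0 - press / sst


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class QsprMLR:
    """Ordinary-least-squares QSPR model with intercept.

    Parameters
    ----------
    X : (n, k) descriptor matrix (no intercept column).
    y : (n,) response, conventionally log10 of the initial rate.
    ids, feature_names : optional row / column labels.
    response_sign : +1 for log10(r0), -1 for the reciprocal convention.
    """

    def __init__(self, X, y, ids: Sequence[str] | None = None,
                 feature_names: Sequence[str] | None = None,
                 response_sign: int = +1):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        y = np.asarray(y, dtype=float)
        if len(X) != len(y):
            raise ValueError("X and y disagree on the number of rows")
        if np.isnan(X).any() or np.isnan(y).any():
            raise ValueError("missing values are not allowed")
        if np.any(X.std(axis=0) == 0):
            dead = np.flatnonzero(X.std(axis=0) == 0)
            raise ValueError(f"constant descriptor column(s) {dead.tolist()}")
        n, k = X.shape
        if n <= k + 2:
            raise DomainError(f"need n > k + 2 (n={n}, k={k})")
        self.X = X
        self.y = y
        self.nobs, self.k = n, k
        self.ids = list(ids) if ids is not None else [str(i) for i in range(n)]
        self.feature_names = (list(feature_names) if feature_names is not None
                              else [f"D{j + 1}" for j in range(k)])
        self.response_sign = response_sign

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, response: str = "y",
                       descriptors: Sequence[str] | None = None,
                       id_col: str | None = None,
                       response_sign: int = +1) -> "QsprMLR":
        if descriptors is None:
            drop = {response, id_col, "split"}
            descriptors = [c for c in df.columns if c not in drop]
        ids = df[id_col].astype(str).tolist() if id_col else \
            df.index.astype(str).tolist()
        return cls(df[descriptors].to_numpy(), df[response].to_numpy(),
                   ids=ids, feature_names=list(descriptors),
                   response_sign=response_sign)

    def fit(self) -> "MLRResults":
        import statsmodels.api as sm
        Xc = _design(self.X)
        if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
            _qr_ols(Xc, self.y)  # raises SingularityError naming columns
        res = sm.OLS(self.y, Xc).fit()
        hat = res.get_influence().hat_matrix_diag
        return MLRResults(model=self, _sm=res, hat=np.asarray(hat))


@dataclass
class MLRResults:
    """Fitted-model container: estimates, uncertainties, diagnostics."""

    model: QsprMLR
    _sm: object
    hat: np.ndarray

    # -- basic quantities ---------------------------------------------------
    @property
    def params(self) -> np.ndarray:
        """(k+1,) coefficients; element 0 is the intercept."""
        return np.asarray(self._sm.params)

    @property
    def bse(self) -> np.ndarray:
        return np.asarray(self._sm.bse)

    @property
    def resid(self) -> np.ndarray:
        return np.asarray(self._sm.resid)

    @property
    def rsquared(self) -> float:
        return float(self._sm.rsquared)

    @property
    def s(self) -> float:
        """Residual standard error, sqrt(SSE / (n - k - 1)), in log units."""
        n, k = self.model.nobs, self.model.k
        return float(np.sqrt((self.resid**2).sum() / (n - k - 1)))

    @property
    def fvalue(self) -> float:
        """F = (R^2/k) / ((1-R^2)/(n-k-1)) with (k, n-k-1) df."""
        n, k = self.model.nobs, self.model.k
        r2 = self.rsquared
        return float((r2 / k) / ((1.0 - r2) / (n - k - 1)))

    @property
    def sst(self) -> float:
        y = self.model.y
        return float(((y - y.mean())**2).sum())

    def predict(self, X_new) -> np.ndarray:
        return _design(np.asarray(X_new, dtype=float)) @ self.params

    # -- validation ---------------------------------------------------------
    def q2_loo(self) -> float:
        return _press_q2(self.resid, self.hat, self.sst)

    def q2_ext(self, X_test, y_test) -> float:
        """External Q²: 1 - SSE(test) / sum (y_test - mean(y_train))²."""
        y_test = np.asarray(y_test, dtype=float)
        sse = float(((y_test - self.predict(X_test))**2).sum())
        sst = float(((y_test - self.model.y.mean())**2).sum())
        return 1.0 - sse / sst

    def bootstrap_q2(self, B: int = 500, seed: int = DEFAULT_SEED
                     ) -> "BootstrapResult":
        return bootstrap_q2(self.model.X, self.model.y, B=B, seed=seed)

    def y_randomization(self, R: int = 5000, seed: int = DEFAULT_SEED
                        ) -> "YRandomizationResult":
        return y_randomization(self.model.X, self.model.y, R=R, seed=seed)

    def diagnostics(self, n_perm: int = 10_000, seed: int = DEFAULT_SEED
                    ) -> "DiagnosticsReport":
        return residual_diagnostics(self, n_perm=n_perm, seed=seed)

    def importance(self) -> pd.DataFrame:
        return descriptor_importance(self)

    def summary(self) -> str:
        n, k = self.model.nobs, self.model.k
        lines = [
            "QSPR ordinary least squares",
            f"  n = {n}, k = {k} descriptors",
            f"  R^2 = {self.rsquared:.3f}   s = {self.s:.3f}   "
            f"F({k},{n - k - 1}) = {self.fvalue:.1f}",
            "",
            f"  {'term':<28}{'coef':>12}{'std err':>12}{'|t|':>8}",
        ]
        names = ["intercept"] + self.model.feature_names
        for name, b, se in zip(names, self.params, self.bse):
            t = abs(b / se) if se > 0 else float("inf")
            lines.append(f"  {name:<28}{b:>12.4g}{se:>12.4g}{t:>8.1f}")
        return "\n".join(lines)


def fit_mlr(X, y, **kwargs) -> MLRResults:
    """Convenience wrapper: build a :class:`QsprMLR` and fit it."""
    return QsprMLR(X, y, **kwargs).fit()


# ---------------------------------------------------------------------------
# stand-alone validation operations
# ---------------------------------------------------------------------------

def q2_loo(X, y) -> float:
    """Leave-one-out Q² = 1 - PRESS/SST via the hat-diagonal identity.

    Equals the explicit n-refit procedure exactly (tested to 1e-10).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape if X.ndim == 2 else (len(X), 1)
    if n <= k + 2:
        raise DomainError(f"need n > k + 2 (n={n}, k={k})")
    _, resid, hat = _qr_ols(_design(X), y)
    return _press_q2(resid, hat, float(((y - y.mean())**2).sum()))


@dataclass(frozen=True)
class BootstrapResult:
    q2_boo: float            # pooled out-of-bag Q²
    per_resample: np.ndarray  # OOB Q² of each usable resample
    n_skipped: int

    def __float__(self):
        return self.q2_boo


def bootstrap_q2(X, y, B: int = 500, seed: int = DEFAULT_SEED
                 ) -> BootstrapResult:
    """Case-resampling bootstrap Q².

    Each of the B resamples refits the model and predicts its out-of-bag
    rows; squared errors are pooled over all OOB predictions and compared
    with squared deviations from the full-sample mean.  Resamples with
    fewer than k+2 distinct rows (or no OOB rows) are skipped and counted.
    """
    if B < 1:
        raise DomainError("B must be >= 1")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    rng = np.random.default_rng(seed)
    ybar = y.mean()
    sse_pool = sst_pool = 0.0
    per = []
    skipped = 0
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), idx)
        if len(np.unique(idx)) < k + 2 or oob.size == 0:
            skipped += 1
            continue
        try:
            beta, _, _ = _qr_ols(_design(X[idx]), y[idx])
        except SingularityError:
            skipped += 1
            continue
        pred = _design(X[oob]) @ beta
        sse = float(((y[oob] - pred)**2).sum())
        sst = float(((y[oob] - ybar)**2).sum())
        sse_pool += sse
        sst_pool += sst
        per.append(1.0 - sse / sst if sst > 0 else np.nan)
    if sst_pool == 0:
        raise DomainError("no usable bootstrap resamples")
    return BootstrapResult(q2_boo=1.0 - sse_pool / sst_pool,
                           per_resample=np.asarray(per), n_skipped=skipped)


@dataclass(frozen=True)
class YRandomizationResult:
    mean_r2: float
    mean_q2: float
    max_r2: float
    true_r2: float
    true_r2_percentile: float  # % of null R² below the true R²
    r2_samples: np.ndarray
    q2_samples: np.ndarray


def y_randomization(X, y, R: int = 5000, seed: int = DEFAULT_SEED
                    ) -> YRandomizationResult:
    """Chance-correlation null: refit after permuting the response R times.

    Under permutation the expectation of R² is k/(n-1) for a full-rank
    design; the summaries report the mean and maximum null R², the mean
    null Q²_LOO, and the percentile of the unpermuted model's R² in the
    null distribution.  Fully vectorized via the fixed hat matrix.
    """
    if R < 1:
        raise DomainError("R must be >= 1")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    rng = np.random.default_rng(seed)
    Xc = _design(X)
    Q, Rmat = np.linalg.qr(Xc)
    if np.any(np.abs(np.diag(Rmat)) < 1e-10):
        raise SingularityError("rank-deficient design in y_randomization")
    hat = (Q**2).sum(axis=1)
    if np.any(hat >= 1 - 1e-12):
        raise DomainError("degenerate leverage in y_randomization")

    perms = np.stack([rng.permutation(y) for _ in range(R)], axis=1)  # n x R
    E = perms - Q @ (Q.T @ perms)
    sst = ((perms - perms.mean(axis=0))**2).sum(axis=0)  # constant, but exact
    r2 = 1.0 - (E**2).sum(axis=0) / sst
    press = ((E / (1.0 - hat)[:, None])**2).sum(axis=0)
    q2 = 1.0 - press / sst

    e_true = y - Q @ (Q.T @ y)
    sst_true = float(((y - y.mean())**2).sum())
    true_r2 = 1.0 - float((e_true**2).sum()) / sst_true
    return YRandomizationResult(
        mean_r2=float(r2.mean()), mean_q2=float(q2.mean()),
        max_r2=float(r2.max()), true_r2=true_r2,
        true_r2_percentile=float((r2 < true_r2).mean() * 100.0),
        r2_samples=r2, q2_samples=q2)


@dataclass(frozen=True)
class DiagnosticsReport:
    shapiro_w: float
    shapiro_p: float
    durbin_watson: float
    durbin_watson_p: float
    vif: np.ndarray
    dw_defined: bool = True


def residual_diagnostics(fit: MLRResults, n_perm: int = 10_000,
                         seed: int = DEFAULT_SEED) -> DiagnosticsReport:
    """Shapiro–Wilk normality, Durbin–Watson independence, VIF collinearity.

    The Durbin–Watson p-value is obtained by permuting the residual order
    (two-sided around the null centre 2), since the statistic's exact null
    depends on the design.  VIF_j = 1/(1-R²_j) from the auxiliary regression
    of descriptor j on the others (VIF of a single-descriptor model is 1).
    """
    e = fit.resid
    if np.allclose(e, e[0]):
        return DiagnosticsReport(np.nan, np.nan, np.nan, np.nan,
                                 _vif(fit.model.X), dw_defined=False)
    if len(e) < 3:
        raise DomainError("Shapiro-Wilk needs n >= 3 residuals")
    w, p_sw = stats.shapiro(e)
    from statsmodels.stats.stattools import durbin_watson
    d = float(durbin_watson(e))
    rng = np.random.default_rng(seed)
    stat = abs(d - 2.0)
    count = 0
    for _ in range(n_perm):
        ep = rng.permutation(e)
        dp = float(((np.diff(ep))**2).sum() / (ep**2).sum())
        if abs(dp - 2.0) >= stat:
            count += 1
    p_dw = (count + 1) / (n_perm + 1)
    return DiagnosticsReport(float(w), float(p_sw), d, p_dw, _vif(fit.model.X))


def _vif(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    if k == 1:
        return np.ones(1)
    out = np.empty(k)
    for j in range(k):
        others = np.delete(X, j, axis=1)
        _, resid, _ = _qr_ols(_design(others), X[:, j])
        sse = float((resid**2).sum())
        sst = float(((X[:, j] - X[:, j].mean())**2).sum())
        out[j] = sst / sse if sse > 0 else np.inf  # = 1/(1-R²_j)
    return out


def descriptor_importance(fit: MLRResults) -> pd.DataFrame:
    """Per-descriptor importance |b_j / se_j| and normalized % shares.

    The intercept is excluded; a zero standard error is flagged as
    infinite importance.
    """
    b = fit.params[1:]
    se = fit.bse[1:]
    with np.errstate(divide="ignore"):
        imp = np.where(se > 0, np.abs(b) / np.where(se > 0, se, 1.0), np.inf)
    finite = imp[np.isfinite(imp)]
    total = finite.sum()
    share = np.where(np.isfinite(imp) & (total > 0), imp / total * 100.0,
                     np.nan)
    return pd.DataFrame({"importance": imp, "share_pct": share},
                        index=fit.model.feature_names)


# ---------------------------------------------------------------------------
# genetic-algorithm subset selection
# ---------------------------------------------------------------------------

def _fitness_q2(Xpool: np.ndarray, y: np.ndarray, cols: tuple[int, ...],
                sst: float) -> tuple[float, float]:
    Xc = _design(Xpool[:, cols])
    try:
        _, resid, hat = _qr_ols(Xc, y)
        q2 = _press_q2(resid, hat, sst)
    except (SingularityError, DomainError):
        return -np.inf, -np.inf
    r2 = 1.0 - float((resid**2).sum()) / sst
    return q2, r2


def ga_select(X, y, model_size: int = 4, generations: int = 100,
              pop_size: int = 200, mutation_rate: float = 0.01,
              crossover_rate: float = 0.5, tournament: int = 3,
              seed: int = DEFAULT_SEED, X_test=None, y_test=None,
              feature_names: Sequence[str] | None = None) -> pd.DataFrame:
    """Genetic-algorithm descriptor-subset selection with Q²_LOO fitness.

    Chromosomes are fixed-size column subsets.  Tournament selection,
    uniform crossover at ``crossover_rate``, per-gene mutation at
    ``mutation_rate``, and single-individual elitism.  Fitness is the
    leave-one-out Q² on the training rows only.  Returns the final
    population (descriptor indices with R², Q²_LOO and, when a test set is
    supplied, Q²_EXT), sorted best first.  Defaults are desk-scale; the
    literature-scale search (10,000 x 1,000) is reachable by arguments.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if model_size > p:
        raise DomainError(f"model_size {model_size} exceeds pool width {p}")
    if n <= model_size + 2:
        raise DomainError("too few rows for the requested model size")
    rng = np.random.default_rng(seed)
    sst = float(((y - y.mean())**2).sum())

    cache: dict[tuple[int, ...], tuple[float, float]] = {}

    def ev(ch: tuple[int, ...]) -> tuple[float, float]:
        if ch not in cache:
            cache[ch] = _fitness_q2(X, y, ch, sst)
        return cache[ch]

    pop = [tuple(sorted(rng.choice(p, size=model_size, replace=False)))
           for _ in range(pop_size)]
    best_trace = []
    for _ in range(generations):
        fits = np.array([ev(c)[0] for c in pop])
        best_trace.append(float(fits.max()))
        elite = pop[int(np.argmax(fits))]
        new_pop = [elite]
        while len(new_pop) < pop_size:
            def pick():
                cand = rng.integers(0, pop_size, size=tournament)
                return pop[cand[np.argmax(fits[cand])]]
            p1, p2 = pick(), pick()
            if rng.random() < crossover_rate:
                union = np.array(sorted(set(p1) | set(p2)))
                child = tuple(sorted(rng.choice(union, size=model_size,
                                                replace=False)))
            else:
                child = p1
            if mutation_rate > 0:
                genes = list(child)
                for g in range(model_size):
                    if rng.random() < mutation_rate:
                        pool_free = np.setdiff1d(np.arange(p), genes)
                        genes[g] = int(rng.choice(pool_free))
                child = tuple(sorted(genes))
            new_pop.append(child)
        pop = new_pop

    rows = []
    seen = set()
    for ch in pop:
        if ch in seen:
            continue
        seen.add(ch)
        q2, r2 = ev(ch)
        row = {"columns": ch, "q2_loo": q2, "r2": r2}
        if X_test is not None and y_test is not None:
            res = fit_mlr(X[:, ch], y)
            row["q2_ext"] = res.q2_ext(np.asarray(X_test)[:, ch], y_test)
        rows.append(row)
    df = pd.DataFrame(rows).sort_values("q2_loo", ascending=False,
                                        ignore_index=True)
    if feature_names is not None:
        df["names"] = df["columns"].map(
            lambda ch: tuple(feature_names[c] for c in ch))
    df.attrs["best_trace"] = best_trace  # per-generation best fitness
    return df


# ---------------------------------------------------------------------------
# random-split robustness study
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RandomSplitSummary:
    median: dict[str, float]
    iqr: dict[str, tuple[float, float]]
    n_used: int
    n_skipped: int
    samples: pd.DataFrame


def random_split_study(X, y, n_splits: int = 1000, train_n: int = 25,
                       seed: int = DEFAULT_SEED) -> RandomSplitSummary:
    """Repeated random train/test splits at fixed model columns.

    Each split refits the model on ``train_n`` rows and evaluates R²,
    Q²_LOO (training) and Q²_EXT (held-out part); the summary reports
    medians and interquartile ranges.  Splits with a constant training
    response or a degenerate fit are skipped and counted.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    if train_n <= k + 2:
        raise DomainError("train_n must exceed k + 2")
    if train_n >= n:
        raise DomainError("train_n must leave a nonempty test part")
    rng = np.random.default_rng(seed)
    recs = []
    skipped = 0
    for _ in range(n_splits):
        perm = rng.permutation(n)
        tr, te = perm[:train_n], perm[train_n:]
        if np.allclose(y[tr], y[tr][0]):
            skipped += 1
            continue
        try:
            res = fit_mlr(X[tr], y[tr])
            recs.append({"r2": res.rsquared, "q2_loo": res.q2_loo(),
                         "q2_ext": res.q2_ext(X[te], y[te])})
        except (SingularityError, DomainError, ValueError):
            skipped += 1
    if not recs:
        raise DomainError("all splits degenerate")
    df = pd.DataFrame(recs)
    med = {c: float(df[c].median()) for c in df.columns}
    iqr = {c: (float(df[c].quantile(0.25)), float(df[c].quantile(0.75)))
           for c in df.columns}
    return RandomSplitSummary(median=med, iqr=iqr, n_used=len(df),
                              n_skipped=skipped, samples=df)
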