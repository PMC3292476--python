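"""Logistic classification of variant candidates, and its training machinery.

The classifier is a plain logistic regression: given covariates x and
coefficients beta, the probability that a candidate is a true variant is

    p = 1 / (1 + exp(-(beta0 + sum_i beta_i x_i)))

Fitting follows the semi-automated workflow used to build the shipped
models: maximum-likelihood fit by iteratively reweighted least squares
(IRLS), AIC-guided bidirectional stepwise variable selection, iterative
removal of non-significant terms guided by single-term likelihood-ratio
tests, percentile-bootstrap confidence intervals on the coefficients, and
repeated split-half cross-validation summarized as precision/sensitivity
curves over a cutoff grid.

The modelling surface mirrors statsmodels: :class:`VariantLogit` is built
from data (``from_dataframe``), ``fit()`` returns a
:class:`VariantLogitResults` carrying estimates, standard errors, Wald
z/p-values and a ``summary()`` table; cross-validation and the bootstrap
hang off the same labeled table.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

__all__ = [
    "LogisticModel",
    "VariantLogit",
    "VariantLogitResults",
    "PerfectSeparationError",
    "SingularDesignError",
    "CvResult",
    "CoefCI",
    "stepwise_select",
    "drop_nonsignificant",
    "cross_validate",
    "bootstrap_ci",
    "save_model",
    "load_model",
    "labels_to_binary",
]

DEFAULT_CUTOFF_GRID = np.round(np.arange(0.0, 1.0001, 0.01), 2)


class PerfectSeparationError(RuntimeError):
    """The likelihood is unbounded: a hyperplane separates the classes."""


class SingularDesignError(ValueError):
    """The design matrix is rank-deficient."""

    def __init__(self, columns: Sequence[str]):
        self.columns = list(columns)
        super().__init__(f"collinear/constant design columns: {', '.join(self.columns)}")


# ---------------------------------------------------------------------------
# the deployable model object


@dataclass
class LogisticModel:
    """Named coefficients of a trained classifier; scores candidates to p."""

    variable_names: tuple[str, ...]
    intercept: float
    coefficients: tuple[float, ...]
    platform_tag: str = "synthetic"
    trained_on: str = ""

    def __post_init__(self) -> None:
        self.variable_names = tuple(self.variable_names)
        self.coefficients = tuple(float(c) for c in self.coefficients)
        if len(self.coefficients) != len(self.variable_names):
            raise ValueError("coefficients and variable_names lengths differ")
        vals = (self.intercept, *self.coefficients)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("model parameters must be finite")

    def score(self, features: Mapping[str, float]) -> float:
        """p that the candidate is a true variant; errors name any missing variable."""
        eta = self.intercept
        for name, beta in zip(self.variable_names, self.coefficients):
            try:
                x = features[name]
            except KeyError:
                raise KeyError(f"feature vector missing variable {name!r}") from None
            eta += beta * x
        return float(expit(eta))

    def score_matrix(self, X: np.ndarray) -> np.ndarray:
        """Vectorized scoring; columns of X follow ``variable_names`` order."""
        X = np.asarray(X, dtype=float)
        return expit(self.intercept + X @ np.asarray(self.coefficients))

    def score_frame(self, df: pd.DataFrame) -> np.ndarray:
        missing = [v for v in self.variable_names if v not in df.columns]
        if missing:
            raise KeyError(f"feature table missing variables {missing}")
        return self.score_matrix(df.loc[:, list(self.variable_names)].to_numpy())


def save_model(model: LogisticModel, path) -> None:
    payload = {
        "variables": list(model.variable_names),
        "intercept": model.intercept,
        "coefficients": list(model.coefficients),
        "platform": model.platform_tag,
        "provenance": model.trained_on,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def load_model(path) -> LogisticModel:
    with open(path) as fh:
        payload = json.load(fh)
    try:
        model = LogisticModel(
            variable_names=tuple(payload["variables"]),
            intercept=float(payload["intercept"]),
            coefficients=tuple(payload["coefficients"]),
            platform_tag=str(payload.get("platform", "")),
            trained_on=str(payload.get("provenance", "")),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ValueError(f"invalid model file {path}: {exc}") from exc
    return model


def labels_to_binary(labels) -> np.ndarray:
    """Map TP/FP (or 1/0, True/False) labels to a float {0,1} vector."""
    mapping = {"TP": 1.0, "FP": 0.0, 1: 1.0, 0: 0.0, True: 1.0, False: 0.0,
               "1": 1.0, "0": 0.0}
    out = np.empty(len(labels), dtype=float)
    for i, lab in enumerate(labels):
        try:
            out[i] = mapping[lab]
        except KeyError:
            raise ValueError(f"unrecognized label {lab!r} (expected TP/FP)") from None
    return out


# ---------------------------------------------------------------------------
# fitting


def _check_design(X: np.ndarray, names: Sequence[str]) -> None:
    # constant columns (other than the intercept) and collinearity, reported
    # by name via pivoted QR
    n, k = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < k:
        from scipy.linalg import qr

        _, r, piv = qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(n, k) * np.finfo(float).eps
        bad = [names[piv[i]] for i in range(len(diag)) if diag[i] <= tol]
        bad += [names[p] for p in piv[len(diag):]]
        raise SingularDesignError(bad or list(names))


def _log_likelihood(y: np.ndarray, eta: np.ndarray) -> float:
    # numerically stable Bernoulli log-likelihood
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _irls(
    y: np.ndarray,
    X: np.ndarray,
    tol: float = 1e-8,
    maxiter: int = 100,
    check_separation: bool = True,
):
    """IRLS for the Bernoulli GLM with logit link.

    Returns (beta, llf, converged, n_iter).  Convergence is declared when
    the log-likelihood improves by less than ``tol``.
    """
    n, k = X.shape
    beta = np.zeros(k)
    llf = _log_likelihood(y, X @ beta)
    converged = False
    it = 0
    for it in range(1, maxiter + 1):
        eta = X @ beta
        mu = expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        WX = X * w[:, None]
        try:
            beta_new = np.linalg.solve(X.T @ WX, X.T @ (w * z))
        except np.linalg.LinAlgError:
            beta_new, *_ = np.linalg.lstsq(np.sqrt(w)[:, None] * X,
                                           np.sqrt(w) * z, rcond=None)
        llf_new = _log_likelihood(y, X @ beta_new)
        # step-halving if the full step decreases the likelihood
        step = 1.0
        while llf_new < llf - 1e-12 and step > 1e-4:
            step /= 2.0
            beta_try = beta + step * (beta_new - beta)
            llf_new = _log_likelihood(y, X @ beta_try)
            if llf_new >= llf - 1e-12:
                beta_new = beta_try
        improved = llf_new - llf
        beta, llf = beta_new, llf_new
        if abs(improved) < tol:
            converged = True
            break
    if check_separation:
        mu = expit(X @ beta)
        if np.all(np.abs(y - mu) < 1e-8):
            raise PerfectSeparationError(
                "perfect separation: fitted probabilities are all 0 or 1; "
                "the MLE does not exist"
            )
    return beta, llf, converged, it


class VariantLogit:
    """Logistic regression model of TP/FP status on candidate covariates.

    Parameters
    ----------
    endog : array-like of {0,1}
        1 for true-positive examples, 0 for false positives.
    exog : array-like, shape (n, k)
        Covariates, without an intercept column (one is added).
    variable_names : sequence of str
    """

    def __init__(self, endog, exog, variable_names: Sequence[str]):
        self.endog = np.asarray(endog, dtype=float).ravel()
        exog = np.asarray(exog, dtype=float)
        if exog.ndim == 1:
            exog = exog[:, None]
        self.exog = exog
        self.variable_names = tuple(variable_names)
        if self.exog.shape[1] != len(self.variable_names):
            raise ValueError("exog width != number of variable names")
        if self.exog.shape[0] != self.endog.shape[0]:
            raise ValueError("endog/exog length mismatch")
        if not np.isfinite(self.exog).all() or not np.isfinite(self.endog).all():
            raise ValueError("non-finite values in design")
        if set(np.unique(self.endog)) - {0.0, 1.0}:
            raise ValueError("endog must be binary 0/1")

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        variables: Sequence[str] | None = None,
        label_col: str = "label",
    ) -> "VariantLogit":
        if variables is None:
            variables = [c for c in df.columns if c != label_col]
        y = labels_to_binary(df[label_col].tolist())
        X = df.loc[:, list(variables)].to_numpy(dtype=float)
        return cls(y, X, variables)

    @property
    def _design(self) -> np.ndarray:
        return np.column_stack([np.ones(len(self.endog)), self.exog])

    def fit(
        self,
        tol: float = 1e-8,
        maxiter: int = 100,
        check_separation: bool = True,
    ) -> "VariantLogitResults":
        """Maximum-likelihood fit by IRLS.

        Raises :class:`PerfectSeparationError` when the MLE does not exist
        and :class:`SingularDesignError` (naming the offending columns) for
        rank-deficient designs.  ``check_separation=False`` returns the
        parameters at the iteration cap instead of raising, which is what
        the cross-validation refits use.
        """
        n1 = int(self.endog.sum())
        if check_separation and (n1 < 2 or len(self.endog) - n1 < 2):
            raise ValueError("need at least 2 examples of each class")
        X = self._design
        names = ["const", *self.variable_names]
        if check_separation:
            for j, name in enumerate(names[1:], start=1):
                if np.ptp(X[:, j]) == 0.0:
                    raise SingularDesignError([name])
            _check_design(X, names)
        beta, llf, converged, n_iter = _irls(
            self.endog, X, tol=tol, maxiter=maxiter,
            check_separation=check_separation,
        )
        mu = expit(X @ beta)
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        xtwx = X.T @ (X * w[:, None])
        try:
            cov = np.linalg.inv(xtwx)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(xtwx)
        return VariantLogitResults(
            model=self,
            params=beta,
            cov_params=cov,
            llf=llf,
            converged=converged,
            n_iter=n_iter,
        )


@dataclass
class VariantLogitResults:
    """Fit results: estimates, uncertainties, diagnostics."""

    model: VariantLogit
    params: np.ndarray  # [intercept, coefficients...]
    cov_params: np.ndarray
    llf: float
    converged: bool
    n_iter: int

    @property
    def names(self) -> list[str]:
        return ["const", *self.model.variable_names]

    @property
    def nobs(self) -> int:
        return len(self.model.endog)

    @property
    def df_model(self) -> int:
        return len(self.params) - 1

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.cov_params), 0.0, None))

    @property
    def zvalues(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.params / self.bse

    @property
    def pvalues(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.zvalues))

    @property
    def aic(self) -> float:
        return 2.0 * len(self.params) - 2.0 * self.llf

    def predict(self, X=None) -> np.ndarray:
        design = self.model._design if X is None else np.column_stack(
            [np.ones(len(X)), np.asarray(X, dtype=float)]
        )
        return expit(design @ self.params)

    def to_model(
        self, platform_tag: str = "synthetic", trained_on: str = ""
    ) -> LogisticModel:
        return LogisticModel(
            variable_names=self.model.variable_names,
            intercept=float(self.params[0]),
            coefficients=tuple(float(b) for b in self.params[1:]),
            platform_tag=platform_tag,
            trained_on=trained_on,
        )

    def summary(self) -> str:
        """Plain-text coefficient table (estimate, SE, z, two-sided p)."""
        lines = [
            "Logistic regression (IRLS), "
            f"n={self.nobs}, llf={self.llf:.3f}, AIC={self.aic:.3f}, "
            f"converged={self.converged} ({self.n_iter} iter)",
            f"{'variable':<20}{'coef':>12}{'std err':>12}{'z':>10}{'P>|z|':>12}",
        ]
        for name, b, se, z, p in zip(
            self.names, self.params, self.bse, self.zvalues, self.pvalues
        ):
            p_str = "< 2e-16" if p < 2e-16 else f"{p:.3g}"
            lines.append(f"{name:<20}{b:>12.4f}{se:>12.4f}{z:>10.2f}{p_str:>12}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# variable selection


def _fit_subset(
    df: pd.DataFrame, variables: Sequence[str], label_col: str, **kw
) -> VariantLogitResults:
    return VariantLogit.from_dataframe(df, variables, label_col).fit(**kw)


def stepwise_select(
    df: pd.DataFrame,
    candidate_variables: Sequence[str],
    label_col: str = "label",
) -> VariantLogitResults:
    """AIC-guided bidirectional stepwise search starting from the full model.

    At each step every single-variable deletion and re-addition is scored by
    AIC and the best improvement is taken; the search stops at a local AIC
    minimum.  Deterministic given the input variable order (ties keep the
    earliest move).  Returns the results of the AIC-minimal model visited;
    an empty selection yields the intercept-only model.
    """
    if len(candidate_variables) < 2:
        raise ValueError("need at least 2 candidate variables")
    current = list(candidate_variables)
    best = _fit_subset(df, current, label_col)
    while True:
        moves: list[tuple[float, list[str]]] = []
        for v in current:
            trial = [c for c in current if c != v]
            res = (
                _fit_subset(df, trial, label_col)
                if trial
                else VariantLogit.from_dataframe(
                    df, [], label_col
                ).fit(check_separation=False)
            )
            moves.append((res.aic, trial, res))
        for v in candidate_variables:
            if v not in current:
                trial = current + [v]
                res = _fit_subset(df, trial, label_col)
                moves.append((res.aic, trial, res))
        if not moves:
            break
        best_aic, best_set, best_res = min(moves, key=lambda m: m[0])
        if best_aic < best.aic - 1e-9:
            current, best = best_set, best_res
        else:
            break
    return best


def lr_drop1(
    df: pd.DataFrame, variables: Sequence[str], label_col: str = "label"
) -> pd.DataFrame:
    """Single-term deletion likelihood-ratio tests for each variable."""
    full = _fit_subset(df, variables, label_col)
    rows = []
    for v in variables:
        reduced_vars = [c for c in variables if c != v]
        if reduced_vars:
            reduced = _fit_subset(df, reduced_vars, label_col)
            llf0 = reduced.llf
        else:
            y = labels_to_binary(df[label_col].tolist())
            pbar = np.clip(y.mean(), 1e-12, 1 - 1e-12)
            llf0 = float(np.sum(y * np.log(pbar) + (1 - y) * np.log(1 - pbar)))
        lr = 2.0 * (full.llf - llf0)
        rows.append((v, lr, stats.chi2.sf(max(lr, 0.0), df=1)))
    return pd.DataFrame(rows, columns=["variable", "lr_stat", "p_value"])


def drop_nonsignificant(
    df: pd.DataFrame,
    variables: Sequence[str],
    alpha: float = 0.05,
    label_col: str = "label",
) -> VariantLogitResults:
    """Iteratively remove the least significant term while its LR p > alpha.

    Refits after every removal; idempotent once every remaining term tests
    significant.
    """
    current = list(variables)
    while len(current) > 1:
        table = lr_drop1(df, current, label_col)
        worst = table.loc[table["p_value"].idxmax()]
        if worst["p_value"] <= alpha:
            break
        current.remove(worst["variable"])
    return _fit_subset(df, current, label_col)


# ---------------------------------------------------------------------------
# cross-validation


def precision_sensitivity_curve(
    y: np.ndarray, scores: np.ndarray, cutoff_grid: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Precision TP/(TP+FP) and sensitivity TP/(TP+FN) per cutoff.

    A call is positive when its score >= cutoff.  Precision is NaN at
    cutoffs where nothing is called.
    """
    y = np.asarray(y, dtype=bool)
    order = np.argsort(scores, kind="stable")
    s = scores[order]
    yt = y[order]
    n_pos = int(yt.sum())
    # cumulative TP among scores >= cutoff via searchsorted
    csum_tp = np.concatenate([[0], np.cumsum(yt[::-1])])[::-1]
    idx = np.searchsorted(s, cutoff_grid, side="left")
    tp = csum_tp[idx].astype(float)
    called = (len(s) - idx).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(called > 0, tp / called, np.nan)
        sensitivity = tp / n_pos if n_pos else np.full_like(tp, np.nan)
    return precision, sensitivity


@dataclass
class CvResult:
    """Repeated split-half cross-validation, as precision/sensitivity curves."""

    cutoffs: np.ndarray
    replicate_precision: np.ndarray  # (reps, n_cutoffs)
    replicate_sensitivity: np.ndarray
    full_precision: np.ndarray
    full_sensitivity: np.ndarray
    n_replicates: int
    seed: int

    @property
    def mean_precision(self) -> np.ndarray:
        # cutoffs where no replicate called anything stay NaN by design
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.replicate_precision, axis=0)

    @property
    def mean_sensitivity(self) -> np.ndarray:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.replicate_sensitivity, axis=0)

    def at_cutoff(self, cutoff: float) -> dict[str, float]:
        i = int(np.argmin(np.abs(self.cutoffs - cutoff)))
        return {
            "cutoff": float(self.cutoffs[i]),
            "mean_precision": float(self.mean_precision[i]),
            "mean_sensitivity": float(self.mean_sensitivity[i]),
            "full_precision": float(self.full_precision[i]),
            "full_sensitivity": float(self.full_sensitivity[i]),
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cutoff": self.cutoffs,
                "mean_precision": self.mean_precision,
                "mean_sensitivity": self.mean_sensitivity,
                "full_precision": self.full_precision,
                "full_sensitivity": self.full_sensitivity,
            }
        )


def draw_split(
    rng: np.random.Generator, y: np.ndarray, n_train: int, max_attempts: int = 100
) -> tuple[np.ndarray, np.ndarray]:
    """Random train/test partition with both classes on both sides.

    The two index arrays always partition ``range(len(y))``; splits missing
    a class on either side are redrawn.
    """
    n = len(y)
    for _ in range(max_attempts):
        perm = rng.permutation(n)
        tr, te = perm[:n_train], perm[n_train:]
        if 0 < y[tr].sum() < len(tr) and 0 < y[te].sum() < len(te):
            return tr, te
    raise RuntimeError("could not draw a split containing both classes")


def cross_validate(
    df: pd.DataFrame,
    variables: Sequence[str],
    reps: int = 100,
    split: float = 0.5,
    cutoff_grid: np.ndarray | None = None,
    seed: int = 0,
    label_col: str = "label",
) -> CvResult:
    """Repeated split-half cross-validation.

    Per replicate: sample ``split`` of the rows without replacement, refit
    on them, score the held-out rows, and record precision/sensitivity over
    the cutoff grid.  Splits lacking a class on either side are redrawn.
    The full-data curve (fit and evaluated on everything) is the
    no-resampling reference; with a well-specified model the mean replicate
    curve should sit on top of it.
    """
    if reps < 2:
        raise ValueError("reps must be >= 2")
    if cutoff_grid is None:
        cutoff_grid = DEFAULT_CUTOFF_GRID
    cutoff_grid = np.asarray(cutoff_grid, dtype=float)
    rng = np.random.default_rng(seed)
    y = labels_to_binary(df[label_col].tolist())
    X = df.loc[:, list(variables)].to_numpy(dtype=float)
    n = len(y)
    n_train = int(round(n * split))

    full_res = VariantLogit(y, X, variables).fit(check_separation=False)
    full_p, full_s = precision_sensitivity_curve(
        y, full_res.predict(X), cutoff_grid
    )

    prec = np.empty((reps, len(cutoff_grid)))
    sens = np.empty((reps, len(cutoff_grid)))
    for r in range(reps):
        tr, te = draw_split(rng, y, n_train)
        res = VariantLogit(y[tr], X[tr], variables).fit(check_separation=False)
        scores = res.predict(X[te])
        prec[r], sens[r] = precision_sensitivity_curve(y[te], scores, cutoff_grid)
    return CvResult(
        cutoffs=cutoff_grid,
        replicate_precision=prec,
        replicate_sensitivity=sens,
        full_precision=full_p,
        full_sensitivity=full_s,
        n_replicates=reps,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# bootstrap


@dataclass
class CoefCI:
    """Percentile-bootstrap confidence intervals per coefficient."""

    names: list[str]
    point: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    level: float
    reps: int
    n_failed: int
    violations: list[str] = field(default_factory=list)

    def contains(self, name: str, value: float) -> bool:
        i = self.names.index(name)
        return bool(self.lower[i] <= value <= self.upper[i])

    def width(self) -> np.ndarray:
        return self.upper - self.lower

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variable": self.names,
                "estimate": self.point,
                "lower": self.lower,
                "upper": self.upper,
            }
        )


def bootstrap_ci(
    df: pd.DataFrame,
    variables: Sequence[str],
    reps: int = 1000,
    level: float = 0.95,
    seed: int = 0,
    label_col: str = "label",
) -> CoefCI:
    """Case-resampling percentile bootstrap of the coefficient vector.

    Replicates that fail to converge or separate perfectly are discarded;
    more than 10% failures aborts with a diagnostic (a symptom of an
    overfit model, which also shows up as unreasonably wide intervals).
    Interval/point inconsistencies are reported in ``violations`` rather
    than clamped.
    """
    y = labels_to_binary(df[label_col].tolist())
    X = df.loc[:, list(variables)].to_numpy(dtype=float)
    point_res = VariantLogit(y, X, variables).fit()
    rng = np.random.default_rng(seed)
    n = len(y)
    draws = np.empty((reps, len(point_res.params)))
    n_failed = 0
    kept = 0
    for _ in range(reps):
        idx = rng.integers(0, n, size=n)
        yb, Xb = y[idx], X[idx]
        if yb.sum() in (0, n):
            n_failed += 1
            continue
        try:
            res = VariantLogit(yb, Xb, variables).fit(check_separation=True)
        except (PerfectSeparationError, SingularDesignError, np.linalg.LinAlgError):
            n_failed += 1
            continue
        if not res.converged:
            n_failed += 1
            continue
        draws[kept] = res.params
        kept += 1
    if n_failed > 0.10 * reps:
        raise RuntimeError(
            f"bootstrap unstable: {n_failed}/{reps} replicates failed to "
            "converge; the model is likely overfit (expect unreasonably wide "
            "confidence intervals)"
        )
    draws = draws[:kept]
    alpha = (1.0 - level) / 2.0
    lower = np.quantile(draws, alpha, axis=0)
    upper = np.quantile(draws, 1.0 - alpha, axis=0)
    names = point_res.names
    violations = [
        names[i]
        for i in range(len(names))
        if not (lower[i] <= point_res.params[i] <= upper[i])
    ]
    return CoefCI(
        names=names,
        point=point_res.params.copy(),
        lower=lower,
        upper=upper,
        level=level,
        reps=reps,
        n_failed=n_failed,
        violations=violations,
    )
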