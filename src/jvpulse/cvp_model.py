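"""Linear CVP model: fitting, exhaustive AIC selection, prediction, CV, power.

Mean CVP (cmH2O) is modelled as an affine function of the subject's mean
IJV-CSA and the CSA autocorrelation r-values on the sparse lag grid.  The
model is refined by evaluating ALL subsets of the candidate predictors and
keeping the one with minimum AIC,

    AIC = n * ln(RSS / n) + 2 * (k + 1),

with k slope coefficients (Gaussian likelihood, constant terms dropped; the
constants cancel in subset comparison).  Subsets with more than n - 2
predictors are inadmissible.  The exhaustive search runs on precomputed Gram
matrices so one subset costs a single small linear solve; the full 2^20
sweep over {csa_mean, lag20..lag360} is feasible on one CPU.

A fixed-coefficient predictor with the published study coefficients is also
provided, so new feature vectors can be scored without refitting.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from .features import AutocorrFeatures, features_to_frame
from .published import PUBLISHED_COEFFICIENTS, PUBLISHED_INTERCEPT
from .signal_core import SignalValidationError

__all__ = [
    "CvpModel",
    "CrossValReport",
    "PowerReport",
    "SingularDesignError",
    "fit_ols",
    "select_model",
    "predict",
    "predict_published",
    "cross_validate",
    "fit_metrics",
    "posthoc_power",
    "linear_model_aic",
    "save_model",
    "load_model",
    "coefficient_table",
]

FeatureInput = Union[Sequence[AutocorrFeatures], pd.DataFrame]


class SingularDesignError(np.linalg.LinAlgError):
    """Design matrix is rank deficient for the requested predictors."""


@dataclass
class CvpModel:
    """A fitted linear model for mean CVP."""

    selected_predictors: Tuple[str, ...]
    coefficients: dict
    intercept: float
    aic: float
    r_squared: float
    mae: float
    n_subjects: int
    fitted_values: Optional[np.ndarray] = None

    def predict_row(self, row: Mapping[str, float]) -> float:
        total = self.intercept
        for name in self.selected_predictors:
            if name not in row or (isinstance(row, pd.Series) and pd.isna(row[name])):
                raise SignalValidationError(f"missing predictor {name!r}")
            total += self.coefficients[name] * float(row[name])
        return total


@dataclass
class CrossValReport:
    k: int
    r_squared_cv: float
    mae_cv: float
    fold_assignments: np.ndarray
    seed: int
    predictions: Optional[np.ndarray] = None


@dataclass
class PowerReport:
    cohens_f2: float
    alpha: float
    power: float
    n: int
    n_predictors: int


def _as_frame(features: FeatureInput) -> pd.DataFrame:
    if isinstance(features, pd.DataFrame):
        return features
    return features_to_frame(list(features))


def _design(frame: pd.DataFrame, predictors: Sequence[str]) -> np.ndarray:
    missing = [p for p in predictors if p not in frame.columns]
    if missing:
        raise SignalValidationError(f"missing predictor column(s): {missing}")
    X = frame[list(predictors)].to_numpy(dtype=float)
    return np.column_stack([np.ones(len(frame)), X])


def linear_model_aic(rss: float, n: int, k: int) -> float:
    """Gaussian linear-model AIC up to an additive constant: n ln(RSS/n) + 2(k+1)."""
    if rss <= 0:
        rss = np.finfo(float).tiny  # perfect fit; keep AIC finite and minimal
    return n * math.log(rss / n) + 2 * (k + 1)


def fit_metrics(observed: Sequence[float], predicted: Sequence[float]) -> Tuple[float, float]:
    """(r^2, mae): squared Pearson correlation and mean absolute error."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size < 2:
        raise SignalValidationError("fit_metrics needs equal-length sequences (n >= 2)")
    mae = float(np.mean(np.abs(obs - pred)))
    do, dp = obs - obs.mean(), pred - pred.mean()
    vo, vp = np.dot(do, do), np.dot(dp, dp)
    if vo == 0 or vp == 0:
        raise SignalValidationError("zero variance in observed or predicted values")
    r = np.dot(do, dp) / np.sqrt(vo * vp)
    return float(r * r), mae


def fit_ols(
    features: FeatureInput,
    cvp_means: Sequence[float],
    predictors: Sequence[str],
) -> CvpModel:
    """Ordinary least squares fit of mean CVP on the chosen predictors."""
    frame = _as_frame(features)
    y = np.asarray(cvp_means, dtype=float)
    n = len(frame)
    if len(y) != n:
        raise SignalValidationError("cvp_means length must match the feature table")
    k = len(predictors)
    if n <= k + 1:
        raise SignalValidationError(f"need more subjects than predictors + 1 (n={n}, k={k})")
    Z = _design(frame, predictors)
    if np.linalg.matrix_rank(Z) < Z.shape[1]:
        corr = np.corrcoef(Z[:, 1:], rowvar=False) if k > 1 else np.ones((1, 1))
        collinear = [
            (predictors[i], predictors[j])
            for i in range(k)
            for j in range(i + 1, k)
            if abs(corr[i, j]) > 1 - 1e-10
        ]
        raise SingularDesignError(f"rank-deficient design; collinear predictors: {collinear}")
    beta, _, _, _ = np.linalg.lstsq(Z, y, rcond=None)
    fitted = Z @ beta
    rss = float(np.sum((y - fitted) ** 2))
    if np.var(fitted) > 0:
        r2, mae = fit_metrics(y, fitted)
    else:  # intercept-only model: fitted values are constant
        r2, mae = 0.0, float(np.mean(np.abs(y - fitted)))
    return CvpModel(
        selected_predictors=tuple(predictors),
        coefficients={p: float(b) for p, b in zip(predictors, beta[1:])},
        intercept=float(beta[0]),
        aic=linear_model_aic(rss, n, k),
        r_squared=r2,
        mae=mae,
        n_subjects=n,
        fitted_values=fitted,
    )


def _exhaustive_search(
    G: np.ndarray, c: np.ndarray, yty: float, n: int, p: int, max_size: int
) -> Tuple[float, Tuple[int, ...]]:
    """Minimum-AIC subset via per-subset Gram solves.

    G = Z'Z and c = Z'y for the intercept-augmented full design Z; a subset's
    RSS is y'y - b'c_S with b solved from the corresponding Gram submatrix.
    Subsets are visited in order of increasing size, lexicographically within
    a size, so the first strict minimum implements the tie-break (fewer
    predictors, then lexicographic candidate order).
    """
    best_aic = math.inf
    best: Tuple[int, ...] = ()
    for size in range(0, min(p, max_size) + 1):
        for combo in itertools.combinations(range(p), size):
            idx = np.concatenate(([0], np.asarray(combo, dtype=int) + 1))
            Gs = G[np.ix_(idx, idx)]
            cs = c[idx]
            try:
                b = np.linalg.solve(Gs, cs)
            except np.linalg.LinAlgError:
                continue
            rss = yty - float(b @ cs)
            aic = linear_model_aic(max(rss, 0.0), n, size)
            if aic < best_aic - 1e-12:
                best_aic, best = aic, combo
    return best_aic, best


def select_model(
    features: FeatureInput,
    cvp_means: Sequence[float],
    candidate_predictors: Sequence[str],
    strategy: str = "exhaustive",
    max_predictors: Optional[int] = None,
) -> CvpModel:
    """Subset of the candidates minimizing AIC, refit as a :class:`CvpModel`.

    ``exhaustive`` evaluates every admissible subset (candidate sets up to 20
    predictors); ``greedy`` is a forward-stepwise fallback for larger sets.
    Subsets larger than ``max_predictors`` (default n - 2) are inadmissible.
    """
    if not candidate_predictors:
        raise SignalValidationError("empty candidate predictor set")
    frame = _as_frame(features)
    y = np.asarray(cvp_means, dtype=float)
    n = len(frame)
    p = len(candidate_predictors)
    max_size = n - 2 if max_predictors is None else min(max_predictors, n - 2)

    if strategy == "exhaustive":
        if p > 20:
            raise SignalValidationError(
                "exhaustive strategy limited to 20 candidates; use strategy='greedy'"
            )
        Z = _design(frame, candidate_predictors)
        G = Z.T @ Z
        c = Z.T @ y
        _, combo = _exhaustive_search(G, c, float(y @ y), n, p, max_size)
        chosen = [candidate_predictors[i] for i in combo]
    elif strategy == "greedy":
        chosen = []
        remaining = list(candidate_predictors)
        current = fit_ols(frame, y, chosen).aic
        while remaining and len(chosen) < max_size:
            trials = [(fit_ols(frame, y, chosen + [r]).aic, r) for r in remaining]
            best_aic, best_pred = min(trials, key=lambda t: t[0])
            if best_aic >= current - 1e-12:
                break
            chosen.append(best_pred)
            remaining.remove(best_pred)
            current = best_aic
    else:
        raise SignalValidationError(f"unknown strategy {strategy!r}")
    return fit_ols(frame, y, chosen)


def predict(model: CvpModel, features: Union[AutocorrFeatures, Mapping, pd.DataFrame]) -> Union[float, np.ndarray]:
    """Predicted mean CVP (cmH2O): intercept + sum(coefficient * feature)."""
    if isinstance(features, pd.DataFrame):
        return np.array([model.predict_row(row) for _, row in features.iterrows()])
    if isinstance(features, AutocorrFeatures):
        features = features.as_dict()
    return model.predict_row(features)


def published_model() -> CvpModel:
    """The published refined model as a :class:`CvpModel` (fixed coefficients)."""
    return CvpModel(
        selected_predictors=tuple(PUBLISHED_COEFFICIENTS),
        coefficients=dict(PUBLISHED_COEFFICIENTS),
        intercept=PUBLISHED_INTERCEPT,
        aic=float("nan"),
        r_squared=float("nan"),
        mae=float("nan"),
        n_subjects=34,
    )


def predict_published(features: Union[AutocorrFeatures, Mapping, pd.DataFrame]) -> Union[float, np.ndarray]:
    """Mean CVP (cmH2O) from the published fixed-coefficient linear model."""
    return predict(published_model(), features)


def cross_validate(
    features: FeatureInput,
    cvp_means: Sequence[float],
    predictors: Sequence[str],
    k: int = 10,
    seed: int = 0,
) -> CrossValReport:
    """k-fold CV with a FIXED predictor set; coefficients refit per fold.

    Folds are a seeded uniform shuffle dealt round-robin (sizes differ by at
    most one).  Out-of-fold predictions are pooled; the report's r^2 is the
    squared correlation of pooled predictions with the observations.
    """
    frame = _as_frame(features).reset_index(drop=True)
    y = np.asarray(cvp_means, dtype=float)
    n = len(frame)
    if not (2 <= k <= n):
        raise SignalValidationError(f"k must be in [2, n]; got k={k}, n={n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.empty(n, dtype=int)
    folds[order] = np.arange(n) % k
    pooled = np.empty(n)
    for fold in range(k):
        test = folds == fold
        model = fit_ols(frame.loc[~test], y[~test], predictors)
        preds = predict(model, frame.loc[test])
        pooled[test] = np.atleast_1d(preds)
    r2_cv, mae_cv = fit_metrics(y, pooled)
    return CrossValReport(
        k=k, r_squared_cv=r2_cv, mae_cv=mae_cv, fold_assignments=folds, seed=seed,
        predictions=pooled,
    )


def posthoc_power(
    r_squared: float, n: int, n_predictors: int, alpha: float = 0.05
) -> PowerReport:
    """Post-hoc power for a multiple regression via Cohen's f^2.

    f^2 = r^2 / (1 - r^2); power is taken from the noncentral F distribution
    with df1 = n_predictors, df2 = n - n_predictors - 1 and noncentrality
    lambda = f^2 * n (the dominant convention; approximate by nature).
    """
    if not (0 <= r_squared < 1):
        raise SignalValidationError("r_squared must lie in [0, 1)")
    if n <= n_predictors + 1:
        raise SignalValidationError("n must exceed n_predictors + 1")
    f2 = r_squared / (1.0 - r_squared)
    df1 = n_predictors
    df2 = n - n_predictors - 1
    crit = stats.f.ppf(1 - alpha, df1, df2)
    nc = f2 * n
    power = float(stats.ncf.sf(crit, df1, df2, nc)) if nc > 0 else alpha
    return PowerReport(cohens_f2=f2, alpha=alpha, power=power, n=n, n_predictors=n_predictors)


# ---------------------------------------------------------------------------
# Serialization and reporting


def save_model(model: CvpModel, path) -> None:
    """Flat key-value text: predictor -> coefficient, plus summary scalars."""
    lines = [f"intercept\t{model.intercept!r}"]
    for name in model.selected_predictors:
        lines.append(f"{name}\t{model.coefficients[name]!r}")
    lines += [
        f"aic\t{model.aic!r}",
        f"r_squared\t{model.r_squared!r}",
        f"mae\t{model.mae!r}",
        f"n_subjects\t{model.n_subjects}",
    ]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def load_model(path) -> CvpModel:
    pairs = {}
    order = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            key, value = line.rstrip("\n").split("\t")
            pairs[key] = value
            order.append(key)
    reserved = {"intercept", "aic", "r_squared", "mae", "n_subjects"}
    predictors = tuple(k for k in order if k not in reserved)
    return CvpModel(
        selected_predictors=predictors,
        coefficients={p: float(pairs[p]) for p in predictors},
        intercept=float(pairs["intercept"]),
        aic=float(pairs["aic"]),
        r_squared=float(pairs["r_squared"]),
        mae=float(pairs["mae"]),
        n_subjects=int(pairs["n_subjects"]),
    )


def coefficient_table(
    features: FeatureInput, cvp_means: Sequence[float], predictors: Sequence[str]
) -> pd.DataFrame:
    """Coefficients with 95% CIs and p-values (statsmodels OLS), one row each."""
    import statsmodels.api as sm

    frame = _as_frame(features)
    X = sm.add_constant(frame[list(predictors)].to_numpy(dtype=float))
    res = sm.OLS(np.asarray(cvp_means, dtype=float), X).fit()
    names = ["intercept"] + list(predictors)
    ci = res.conf_int(alpha=0.05)
    return pd.DataFrame(
        {
            "predictor": names,
            "coefficient": res.params,
            "ci_low": ci[:, 0],
            "ci_high": ci[:, 1],
            "p_value": res.pvalues,
        }
    )
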