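"""Per-locus regression models on beta values, cross-validation and metrics.

Each model locus gets its own model predicting its beta value from the
beta values of 1–3 feature loci.  The default family is a logistic
(fractional-response binomial) regression,

    beta_hat = sigmoid(w · x + b),

fitted by iteratively reweighted least squares on the binomial deviance
with the observed betas (clipped away from {0, 1}) as fractional
responses.  An ordinary-least-squares family (prediction clipped to
[0, 1]) is available for comparison.

Performance is summarized by eight cross-validated indicators — Pearson
R, RMSE, MAE, sensitivity, specificity, MCC, accuracy, AUC — computed
on pooled out-of-fold predictions, and each model is categorized by its
CV RMSE into one of four accuracy tiers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from scipy.stats import rankdata

from .arrays_io import MethylationMatrix
from .feature_selection import FeatureAssignment

MODEL_SCHEMA_VERSION = 1

#: minimum complete (y, x) rows required to fit a locus model
MIN_FIT_SAMPLES = 30

#: fractional responses are clipped to [EPS, 1-EPS] before the deviance fit
LOGISTIC_EPS = 1e-6

IRLS_TOL = 1e-8
IRLS_MAX_ITER = 100

CATEGORIES = ("super_high", "high", "medium", "low")

#: upper RMSE bound (exclusive) per category; low is unbounded
_CATEGORY_EDGES = ((0.05, "super_high"), (0.10, "high"), (0.15, "medium"))


class DegenerateFitError(ValueError):
    """The design matrix cannot support a fit (constant feature, rank deficiency)."""


class ConvergenceError(RuntimeError):
    """IRLS failed to converge within the iteration budget."""


def sigmoid(z):
    z = np.asarray(z, dtype=float)
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _design(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X


def fit_logistic(
    y: np.ndarray,
    X: np.ndarray,
    eps: float = LOGISTIC_EPS,
    tol: float = IRLS_TOL,
    max_iter: int = IRLS_MAX_ITER,
) -> tuple[np.ndarray, float]:
    """Fit sigmoid(w·x + b) to fractional responses by IRLS.

    Minimizes the binomial deviance with y clipped to [eps, 1-eps]; the
    objective is convex, so the solution is independent of
    initialization.  Returns ``(w, b)`` with one weight per feature
    column.

    Raises :class:`DegenerateFitError` on a constant feature column and
    :class:`ConvergenceError` if the coefficient change never drops
    below ``tol``.
    """
    X = _design(X)
    y = np.clip(np.asarray(y, dtype=float), eps, 1.0 - eps)
    n, p = X.shape
    if n < p + 1:
        raise DegenerateFitError(f"{n} rows cannot identify {p + 1} parameters")
    if np.any(np.ptp(X, axis=0) == 0):
        raise DegenerateFitError("constant feature column")
    A = np.column_stack([X, np.ones(n)])
    beta = np.zeros(p + 1)
    for _ in range(max_iter):
        eta = A @ beta
        mu = sigmoid(eta)
        wgt = mu * (1.0 - mu)
        wgt = np.maximum(wgt, 1e-12)
        z = eta + (y - mu) / wgt
        WA = A * wgt[:, None]
        try:
            new = np.linalg.solve(A.T @ WA, A.T @ (wgt * z))
        except np.linalg.LinAlgError as exc:
            raise DegenerateFitError("singular IRLS system") from exc
        step = np.max(np.abs(new - beta))
        beta = new
        if step < tol:
            return beta[:p], float(beta[p])
    raise ConvergenceError(f"IRLS did not converge in {max_iter} iterations")


def fit_ols(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, float]:
    """Least-squares fit alpha·x + c; predictions are clipped at predict time."""
    X = _design(X)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if np.any(np.ptp(X, axis=0) == 0):
        raise DegenerateFitError("constant feature column")
    A = np.column_stack([X, np.ones(n)])
    if np.linalg.matrix_rank(A) < p + 1:
        raise DegenerateFitError("rank-deficient design")
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return coef[:p], float(coef[p])


def predict_family(
    family: str, coefficients: np.ndarray, intercept: float, X: np.ndarray
) -> np.ndarray:
    """Model output for a feature matrix: sigmoid link or clipped linear."""
    X = _design(X)
    eta = X @ np.asarray(coefficients, dtype=float) + intercept
    if family == "logistic":
        return sigmoid(eta)
    if family == "ols":
        return np.clip(eta, 0.0, 1.0)
    raise ValueError(f"unknown model family {family!r}")


@dataclass
class CVMetrics:
    """Eight pooled out-of-fold performance indicators.

    Classification metrics binarize at beta > 0.5 (status +1, else −1)
    with the observed status as truth.  Metrics undefined on the data
    (e.g. SE when no observed positives) are NaN, never silently 0.
    """

    r: float
    rmse: float
    mae: float
    se: float
    sp: float
    mcc: float
    acc: float
    auc: float

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


def _auc_mannwhitney(scores: np.ndarray, truth_pos: np.ndarray) -> float:
    """AUC as the Mann-Whitney rank statistic with midrank tie handling."""
    n_pos = int(truth_pos.sum())
    n_neg = truth_pos.size - n_pos
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = rankdata(scores, method="average")
    u = ranks[truth_pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def compute_metrics(predicted: np.ndarray, observed: np.ndarray) -> CVMetrics:
    """Continuous (R, RMSE, MAE) and 0.5-binarized (SE, SP, ACC, MCC, AUC) metrics.

    SE = TP/(TP+FN), SP = TN/(TN+FP); MCC from the confusion counts;
    AUC ranks the continuous predictions against the binarized observed
    status.
    """
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape:
        raise ValueError("predicted and observed must have equal length")
    n = predicted.size
    if n == 0:
        raise ValueError("empty vectors")
    rmse = float(np.sqrt(np.mean((predicted - observed) ** 2)))
    mae = float(np.mean(np.abs(predicted - observed)))
    if np.ptp(predicted) > 0 and np.ptp(observed) > 0:
        r = float(np.corrcoef(predicted, observed)[0, 1])
    else:
        r = float("nan")

    obs_pos = observed > 0.5
    pred_pos = predicted > 0.5
    tp = int(np.sum(obs_pos & pred_pos))
    fn = int(np.sum(obs_pos & ~pred_pos))
    tn = int(np.sum(~obs_pos & ~pred_pos))
    fp = int(np.sum(~obs_pos & pred_pos))
    se = tp / (tp + fn) if (tp + fn) > 0 else float("nan")
    sp = tn / (tn + fp) if (tn + fp) > 0 else float("nan")
    acc = (tp + tn) / n
    denom = (tn + fn) * (tn + fp) * (tp + fn) * (tp + fp)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom > 0 else float("nan")
    auc = _auc_mannwhitney(predicted, obs_pos)
    return CVMetrics(r=r, rmse=rmse, mae=mae, se=float(se), sp=float(sp),
                     mcc=float(mcc), acc=float(acc), auc=auc)


def categorize(rmse: float) -> str:
    """Accuracy tier from cross-validated RMSE.

    super_high: RMSE < 0.05; high: 0.05 ≤ RMSE < 0.1;
    medium: 0.1 ≤ RMSE < 0.15; low: RMSE ≥ 0.15.
    """
    if not np.isfinite(rmse) or rmse < 0:
        raise ValueError(f"RMSE must be a finite non-negative number, got {rmse!r}")
    for edge, name in _CATEGORY_EDGES:
        if rmse < edge:
            return name
    return "low"


@dataclass
class LocusModel:
    """A fitted per-locus model with its CV record."""

    model_probe_id: str
    feature_probe_ids: list[str]
    family: str
    coefficients: list[float]
    intercept: float
    cv_metrics: CVMetrics
    category: str
    n_training_samples: int
    flagged: bool = False
    flag_reason: str = ""

    def predict(self, X: np.ndarray) -> np.ndarray:
        return predict_family(self.family, np.asarray(self.coefficients), self.intercept, X)


def _complete_rows(
    training: MethylationMatrix, target: str, features: list[str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """y, X and the boolean sample mask of rows complete in target and features."""
    y = training.values_for(target)
    X = training.data.loc[features].to_numpy(dtype=float).T  # samples × features
    ok = ~np.isnan(y) & ~np.isnan(X).any(axis=1)
    return y[ok], X[ok], ok


def _fold_indices(n: int, k_folds: int, seed: int) -> list[np.ndarray]:
    rng = np.random.default_rng(seed)
    return np.array_split(rng.permutation(n), k_folds)


def cross_validate(
    model_probe: str,
    assignment: FeatureAssignment,
    training: MethylationMatrix,
    family: str = "logistic",
    feature_mode: str = "cometh",
    k_folds: int = 5,
    seed: int = 1,
    min_fit_samples: int = MIN_FIT_SAMPLES,
) -> tuple[LocusModel, np.ndarray]:
    """Seeded k-fold CV for one locus; returns the refit model and OOF predictions.

    Samples with a missing target or feature value are dropped before
    folding.  Metrics are computed once on the pooled out-of-fold
    predictions; the returned coefficients are refit on all complete
    training rows and the category comes from the pooled CV RMSE.
    """
    features = assignment.feature_probes(feature_mode)
    if not features:
        raise DegenerateFitError(f"no features assigned to {model_probe!r}")
    y, X, _ = _complete_rows(training, model_probe, features)
    n = y.size
    if n < max(k_folds, min_fit_samples):
        raise DegenerateFitError(
            f"{model_probe!r}: only {n} complete rows (need >= {max(k_folds, min_fit_samples)})"
        )
    fit = fit_logistic if family == "logistic" else fit_ols
    oof = np.full(n, np.nan)
    for fold in _fold_indices(n, k_folds, seed):
        mask = np.ones(n, dtype=bool)
        mask[fold] = False
        w, b = fit(y[mask], X[mask])
        oof[fold] = predict_family(family, w, b, X[fold])
    metrics = compute_metrics(oof, y)
    w, b = fit(y, X)
    model = LocusModel(
        model_probe_id=model_probe,
        feature_probe_ids=list(features),
        family=family,
        coefficients=[float(c) for c in np.atleast_1d(w)],
        intercept=float(b),
        cv_metrics=metrics,
        category=categorize(metrics.rmse),
        n_training_samples=n,
    )
    return model, oof


def build_models(
    assignments: dict[str, FeatureAssignment],
    training: MethylationMatrix,
    family: str = "logistic",
    feature_mode: str = "cometh",
    k_folds: int = 5,
    seed: int = 1,
    min_fit_samples: int = MIN_FIT_SAMPLES,
) -> tuple[dict[str, LocusModel], dict[str, str]]:
    """Cross-validate every assigned locus; returns (models, skipped with reason)."""
    models: dict[str, LocusModel] = {}
    skipped: dict[str, str] = {}
    for mp in sorted(assignments):
        try:
            model, _ = cross_validate(
                mp, assignments[mp], training,
                family=family, feature_mode=feature_mode,
                k_folds=k_folds, seed=seed, min_fit_samples=min_fit_samples,
            )
            models[mp] = model
        except (DegenerateFitError, ConvergenceError) as exc:
            skipped[mp] = str(exc)
    return models, skipped


def save_models(models: dict[str, LocusModel], path) -> None:
    """Write models as JSON lines; coefficients keep full precision."""
    with open(path, "w") as fh:
        fh.write(json.dumps({"schema_version": MODEL_SCHEMA_VERSION}) + "\n")
        for mp in sorted(models):
            m = models[mp]
            rec = {
                "model_probe_id": m.model_probe_id,
                "feature_probe_ids": m.feature_probe_ids,
                "family": m.family,
                "coefficients": m.coefficients,
                "intercept": m.intercept,
                "cv_metrics": m.cv_metrics.as_dict(),
                "category": m.category,
                "n_training_samples": m.n_training_samples,
                "flagged": m.flagged,
                "flag_reason": m.flag_reason,
            }
            fh.write(json.dumps(rec, allow_nan=True) + "\n")


def load_models(path) -> dict[str, LocusModel]:
    """Read a model file written by :func:`save_models`."""
    models: dict[str, LocusModel] = {}
    with open(path) as fh:
        header = json.loads(fh.readline())
        version = header.get("schema_version")
        if version != MODEL_SCHEMA_VERSION:
            raise ValueError(
                f"unsupported model file schema version {version!r} "
                f"(expected {MODEL_SCHEMA_VERSION})"
            )
        for line in fh:
            rec = json.loads(line)
            models[rec["model_probe_id"]] = LocusModel(
                model_probe_id=rec["model_probe_id"],
                feature_probe_ids=list(rec["feature_probe_ids"]),
                family=rec["family"],
                coefficients=[float(c) for c in rec["coefficients"]],
                intercept=float(rec["intercept"]),
                cv_metrics=CVMetrics(**rec["cv_metrics"]),
                category=rec["category"],
                n_training_samples=int(rec["n_training_samples"]),
                flagged=bool(rec.get("flagged", False)),
                flag_reason=rec.get("flag_reason", ""),
            )
    return models


def category_report(models: dict[str, LocusModel]):
    """Per-category mean of the eight CV metrics plus locus counts."""
    import pandas as pd

    rows = []
    for cat in CATEGORIES:
        sub = [m for m in models.values() if m.category == cat]
        if not sub:
            continue
        row = {"category": cat, "n_loci": len(sub)}
        for name in ("r", "rmse", "mae", "se", "sp", "mcc", "acc", "auc"):
            row[name] = float(np.nanmean([getattr(m.cv_metrics, name) for m in sub]))
        rows.append(row)
    return pd.DataFrame(rows)
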