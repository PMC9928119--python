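"""Sparse logistic-regression selection of phenotype-predictive brain regions.

This is the analysis stage: region signals are the independent variables,
the binary phenotype the dependent variable, and an L1 (lasso) penalty
shrinks uninformative regions' coefficients exactly to zero so the fitted
model doubles as a variable selector that tolerates the strong positive
multicollinearity variegated expression induces.

Layers, bottom up:

* :func:`fit_lasso` — one penalized fit at a given penalty, on per-region
  standardized predictors with an unpenalized intercept.
* :func:`select_lambda_cv` — stratified k-fold cross-validation of the
  penalty over a geometric grid (deviance loss), with the one-standard-error
  rule as the default since sparse models are the point.
* :func:`refit_excluding` — rerun with the previous top candidate's column
  omitted, the first fallback when a candidate region fails validation.
* :func:`bootstrap_lasso` — split-half bootstrap reliability: many random
  stratified train/test halves, a full CV + fit per half, models filtered by
  the ">50% accuracy on both halves" rule, and signed-coefficient
  frequencies tallied over the accurate models only.
* :func:`baseline_comparison` — bootstrapped unpenalized logistic baselines
  (whole-brain average signal, one focal region, both) to check a candidate
  region is informative beyond global expression level.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold, train_test_split

from . import _glm
from .core_io import PhenotypeTable, RegionSignalMatrix
from .errors import SingleClassError, UnknownRegionError, ValidationError

__all__ = [
    "SparseLogisticModel",
    "BootstrapReport",
    "BaselineReport",
    "fit_lasso",
    "select_lambda_cv",
    "predict",
    "accuracy",
    "refit_excluding",
    "bootstrap_lasso",
    "baseline_comparison",
]


# ---------------------------------------------------------------------------
# model object


@dataclass
class SparseLogisticModel:
    """Intercept + per-region coefficients of one L1-penalized logistic fit.

    Coefficients live on the standardized scale (each predictor centered and
    scaled by its training mean/sd, both stored), so predictions from raw
    inputs first standardize with the stored moments — de-standardized and
    standardized predictions are identical by construction.
    """

    intercept: float
    coef: np.ndarray
    lam: float
    region_ids: list[str]
    feature_means: np.ndarray
    feature_sds: np.ndarray

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValidationError("lambda must be >= 0")
        if not (len(self.coef) == len(self.region_ids) == len(self.feature_means)):
            raise ValidationError("coefficient/region/moment lengths disagree")

    @property
    def selected_regions(self) -> list[str]:
        return [r for r, b in zip(self.region_ids, self.coef) if b != 0.0]

    @property
    def top_region(self) -> str | None:
        """Selected region with the largest |standardized coefficient|."""
        if not self.selected_regions:
            return None
        return self.region_ids[int(np.argmax(np.abs(self.coef)))]

    def raw_coefficients(self) -> tuple[float, np.ndarray]:
        """(intercept, coefficients) on the raw input scale."""
        b_raw = self.coef / self.feature_sds
        b0_raw = self.intercept - float(b_raw @ self.feature_means)
        return b0_raw, b_raw

    def decision_function(self, X_raw: np.ndarray) -> np.ndarray:
        Xs = (np.asarray(X_raw, dtype=np.float64) - self.feature_means) / self.feature_sds
        return self.intercept + Xs @ self.coef

    def predict_proba(self, X_raw: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-np.clip(self.decision_function(X_raw), -35, 35)))

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "coef": self.coef.tolist(),
            "lambda": self.lam,
            "region_ids": list(self.region_ids),
            "feature_means": self.feature_means.tolist(),
            "feature_sds": self.feature_sds.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SparseLogisticModel":
        return cls(
            intercept=float(d["intercept"]),
            coef=np.asarray(d["coef"], dtype=np.float64),
            lam=float(d["lambda"]),
            region_ids=list(d["region_ids"]),
            feature_means=np.asarray(d["feature_means"], dtype=np.float64),
            feature_sds=np.asarray(d["feature_sds"], dtype=np.float64),
        )


# ---------------------------------------------------------------------------
# alignment / standardization helpers


def _design(m: RegionSignalMatrix, y: PhenotypeTable) -> tuple[np.ndarray, np.ndarray]:
    yy = y.aligned_to(m).phenotype
    classes = np.unique(yy)
    if len(classes) < 2:
        raise SingleClassError(f"phenotype has a single class {classes.tolist()}")
    return m.values, yy.astype(np.float64)

def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    if (sd == 0).any():
        raise ValidationError(
            "zero-variance predictor column; drop it first (drop_uninformative_regions)"
        )
    return (X - mu) / sd, mu, sd


# ---------------------------------------------------------------------------
# single fits


def fit_lasso(m: RegionSignalMatrix, y: PhenotypeTable, lam: float) -> SparseLogisticModel:
    """One L1-penalized logistic fit at penalty ``lam``.

    Minimizes ``(1/n)*NLL + lam*||beta||_1`` over standardized predictors
    with an unpenalized intercept; shrunk-out coefficients are exactly zero.
    """
    if lam < 0:
        raise ValidationError("lambda must be >= 0")
    X, yy = _design(m, y)
    Xs, mu, sd = _standardize(X)
    b0, b = _glm.fit_l1_logistic(Xs, yy, lam)
    return SparseLogisticModel(
        intercept=b0, coef=b, lam=float(lam), region_ids=m.regions,
        feature_means=mu, feature_sds=sd,
    )


@dataclass
class CVResult:
    """Cross-validation trace: the grid, per-lambda mean deviance and its
    standard error over folds, and the chosen penalty."""

    grid: np.ndarray
    mean_deviance: np.ndarray
    se_deviance: np.ndarray
    lam: float
    rule: str
    n_folds: int
    seed: int


def select_lambda_cv(
    m: RegionSignalMatrix,
    y: PhenotypeTable,
    n_folds: int = 5,
    grid: np.ndarray | None = None,
    rule: str = "one_se",
    seed: int = 0,
    full_output: bool = False,
) -> float | CVResult:
    """Choose the penalty by stratified k-fold cross-validated deviance.

    ``rule='min'`` returns the deviance-minimizing penalty (ties broken
    toward the larger penalty); ``rule='one_se'`` (default) returns the
    largest penalty whose mean deviance is within one standard error of the
    minimum — the sparser model that is statistically indistinguishable from
    the best one.
    """
    if rule not in ("min", "one_se"):
        raise ValidationError(f"unknown rule {rule!r}")
    if n_folds < 2:
        raise ValidationError("n_folds must be >= 2")
    X, yy = _design(m, y)
    counts = np.bincount(yy.astype(int))
    if counts.min() < n_folds:
        raise SingleClassError(
            f"cannot stratify {n_folds} folds: minority class has {counts.min()} subjects"
        )
    if grid is None:
        Xs_full, _, _ = _standardize(X)
        grid = _glm.default_lambda_grid(Xs_full, yy)
    grid = np.asarray(grid, dtype=np.float64)
    if (grid <= 0).any():
        raise ValidationError("lambda grid must be positive")
    if len(grid) > 1 and not np.all(np.diff(grid) < 0):
        raise ValidationError("lambda grid must be decreasing")

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    dev = np.empty((n_folds, len(grid)))
    for f, (tr, va) in enumerate(skf.split(X, yy)):
        Xs, mu, sd = _standardize_safe(X[tr])
        b0s, bs = (
            _glm.lasso_path(Xs, yy[tr], grid)
            if len(grid) > 1
            else _single_as_path(Xs, yy[tr], grid)
        )
        Xva = (X[va] - mu) / sd
        for k in range(len(grid)):
            eta = b0s[k] + Xva @ bs[k]
            prob = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
            dev[f, k] = _glm.mean_deviance(yy[va], prob)
    mean_dev = dev.mean(axis=0)
    se_dev = dev.std(axis=0, ddof=1) / np.sqrt(n_folds)
    i_min = int(np.argmin(mean_dev))  # first index = largest lambda on ties
    if rule == "min":
        i_sel = i_min
    else:
        thresh = mean_dev[i_min] + se_dev[i_min]
        i_sel = int(np.flatnonzero(mean_dev <= thresh)[0])
    lam = float(grid[i_sel])
    if full_output:
        return CVResult(grid, mean_dev, se_dev, lam, rule, n_folds, seed)
    return lam


def _standardize_safe(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    # within CV folds a column may go constant even if globally it is not;
    # give it unit scale so it contributes nothing rather than failing
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (X - mu) / sd, mu, sd


def _single_as_path(Xs, yy, grid):
    b0, b = _glm.fit_l1_logistic(Xs, yy, float(grid[0]))
    return np.array([b0]), b[None, :]


def fit_lasso_cv(
    m: RegionSignalMatrix,
    y: PhenotypeTable,
    n_folds: int = 5,
    grid: np.ndarray | None = None,
    rule: str = "one_se",
    seed: int = 0,
) -> SparseLogisticModel:
    """CV-select the penalty, then fit on the full data at that penalty."""
    lam = select_lambda_cv(m, y, n_folds=n_folds, grid=grid, rule=rule, seed=seed)
    return fit_lasso(m, y, lam)


# ---------------------------------------------------------------------------
# prediction


def predict(
    model: SparseLogisticModel, m: RegionSignalMatrix, threshold: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Per-subject predicted probability and class (probability > threshold)."""
    missing = [r for r in model.region_ids if r not in m.regions]
    if missing:
        raise UnknownRegionError(f"matrix lacks model region(s): {missing}")
    X = m.subset_regions(model.region_ids).values
    prob = model.predict_proba(X)
    return prob, (prob > threshold).astype(np.int64)


def accuracy(
    model: SparseLogisticModel,
    m: RegionSignalMatrix,
    y: PhenotypeTable,
    balanced: bool = False,
) -> float:
    """Fraction of subjects classified correctly (or mean per-class recall
    when ``balanced=True``)."""
    _, cls = predict(model, m)
    yy = y.aligned_to(m).phenotype
    if not balanced:
        return float(np.mean(cls == yy))
    accs = [np.mean(cls[yy == c] == c) for c in np.unique(yy)]
    return float(np.mean(accs))


# ---------------------------------------------------------------------------
# top-candidate-omitted rerun


def refit_excluding(
    m: RegionSignalMatrix,
    y: PhenotypeTable,
    drop: Sequence[str],
    lam: float | None = None,
    n_folds: int = 5,
    rule: str = "one_se",
    seed: int = 0,
) -> SparseLogisticModel:
    """Rerun the selection with the listed regions' columns omitted.

    Used when the top candidate fails validation: strongly correlated
    runners-up, masked by the sparse fit, surface once the winner is
    removed.  With ``lam=None`` the penalty is re-selected by CV on the
    reduced matrix.
    """
    drop = list(drop)
    missing = [r for r in drop if r not in m.regions]
    if missing:
        raise UnknownRegionError(f"cannot drop unknown region(s): {missing}")
    if len(drop) >= len(m.regions):
        raise ValidationError("cannot drop every region")
    m2 = m.drop_regions(drop)
    if lam is None:
        return fit_lasso_cv(m2, y, n_folds=n_folds, rule=rule, seed=seed)
    return fit_lasso(m2, y, lam)


# ---------------------------------------------------------------------------
# split-half bootstrap reliability


@dataclass
class BootstrapReport:
    """Split-half bootstrap of the full CV + lasso pipeline.

    Per replicate: stratified half/half train–test split, penalty re-selected
    by CV on the training half, fit, and accuracy on both halves.  A model is
    *accurate* when both accuracies strictly exceed 0.5; signed-coefficient
    frequencies are tallied over accurate models only, since inaccurate
    models' supports are noise.
    """

    n_models: int
    train_fraction: float
    rng_seed: int
    region_ids: list[str]
    train_accuracy: np.ndarray
    test_accuracy: np.ndarray
    accurate: np.ndarray  # bool per model
    positive_counts: np.ndarray  # per region, over accurate models
    negative_counts: np.ndarray

    @property
    def n_accurate(self) -> int:
        return int(self.accurate.sum())

    def frequency_table(self) -> list[dict]:
        """Per-region signed-selection frequencies, sorted by positive count."""
        rows = [
            {
                "region_id": r,
                "positive": int(p),
                "negative": int(n),
            }
            for r, p, n in zip(self.region_ids, self.positive_counts, self.negative_counts)
        ]
        return sorted(rows, key=lambda d: (-d["positive"], -d["negative"], d["region_id"]))

    def to_dict(self) -> dict:
        return {
            "n_models": self.n_models,
            "train_fraction": self.train_fraction,
            "rng_seed": self.rng_seed,
            "region_ids": list(self.region_ids),
            "train_accuracy": self.train_accuracy.tolist(),
            "test_accuracy": self.test_accuracy.tolist(),
            "accurate": [bool(a) for a in self.accurate],
            "positive_counts": self.positive_counts.tolist(),
            "negative_counts": self.negative_counts.tolist(),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "BootstrapReport":
        return cls(
            n_models=int(d["n_models"]),
            train_fraction=float(d["train_fraction"]),
            rng_seed=int(d["rng_seed"]),
            region_ids=list(d["region_ids"]),
            train_accuracy=np.asarray(d["train_accuracy"], dtype=np.float64),
            test_accuracy=np.asarray(d["test_accuracy"], dtype=np.float64),
            accurate=np.asarray(d["accurate"], dtype=bool),
            positive_counts=np.asarray(d["positive_counts"], dtype=np.int64),
            negative_counts=np.asarray(d["negative_counts"], dtype=np.int64),
        )


def _stratified_split(y: np.ndarray, train_fraction: float, rs: int):
    idx = np.arange(len(y))
    tr, te = train_test_split(
        idx, train_size=train_fraction, stratify=y, random_state=rs, shuffle=True
    )
    return np.sort(tr), np.sort(te)


def bootstrap_lasso(
    m: RegionSignalMatrix,
    y: PhenotypeTable,
    n_models: int = 100,
    train_fraction: float = 0.5,
    seed: int = 0,
    n_folds: int = 5,
    rule: str = "one_se",
) -> BootstrapReport:
    """Split-half bootstrap reliability analysis of the lasso selection."""
    if not (0 < train_fraction < 1):
        raise ValidationError("train_fraction must lie in (0, 1)")
    X, yy = _design(m, y)
    yi = yy.astype(int)
    n_train_min = np.bincount(yi).min() * train_fraction
    if n_train_min < 1 or np.bincount(yi).min() < n_folds / train_fraction:
        raise ValidationError(
            "too few subjects per class to stratify the split and the inner CV"
        )
    y_aligned = y.aligned_to(m).data
    child_seeds = np.random.SeedSequence(seed).generate_state(n_models) % (2**31 - 1)

    p = len(m.regions)
    train_acc = np.empty(n_models)
    test_acc = np.empty(n_models)
    accurate = np.zeros(n_models, dtype=bool)
    pos = np.zeros(p, dtype=np.int64)
    neg = np.zeros(p, dtype=np.int64)
    for b in range(n_models):
        rs = int(child_seeds[b])
        tr, te = _stratified_split(yi, train_fraction, rs)
        m_tr = RegionSignalMatrix(m.data.iloc[tr], m.normalization_tag)
        m_te = RegionSignalMatrix(m.data.iloc[te], m.normalization_tag)
        y_tr = PhenotypeTable(y_aligned.iloc[tr])
        y_te = PhenotypeTable(y_aligned.iloc[te])
        model = fit_lasso_cv(m_tr, y_tr, n_folds=n_folds, rule=rule, seed=rs)
        train_acc[b] = accuracy(model, m_tr, y_tr)
        test_acc[b] = accuracy(model, m_te, y_te)
        if train_acc[b] > 0.5 and test_acc[b] > 0.5:
            accurate[b] = True
            pos += model.coef > 0
            neg += model.coef < 0
    return BootstrapReport(
        n_models=n_models,
        train_fraction=train_fraction,
        rng_seed=seed,
        region_ids=m.regions,
        train_accuracy=train_acc,
        test_accuracy=test_acc,
        accurate=accurate,
        positive_counts=pos,
        negative_counts=neg,
    )


# ---------------------------------------------------------------------------
# univariate / bivariate baselines


@dataclass
class BaselineReport:
    """Bootstrapped test accuracies of three unpenalized logistic baselines:
    whole-brain average signal, the focal region alone, and both together."""

    focal: str
    n_boot: int
    rng_seed: int
    accuracies: dict  # predictor-set name -> np.ndarray of test accuracies

    def mean(self, name: str) -> float:
        return float(np.mean(self.accuracies[name]))

    def sem(self, name: str) -> float:
        a = self.accuracies[name]
        return float(np.std(a, ddof=1) / np.sqrt(len(a))) if len(a) > 1 else 0.0

    def summary(self) -> dict:
        return {
            name: {"mean": self.mean(name), "sem": self.sem(name)}
            for name in self.accuracies
        }

    def to_dict(self) -> dict:
        return {
            "focal": self.focal,
            "n_boot": self.n_boot,
            "rng_seed": self.rng_seed,
            "accuracies": {k: v.tolist() for k, v in self.accuracies.items()},
            "summary": self.summary(),
        }


def baseline_comparison(
    m: RegionSignalMatrix,
    y: PhenotypeTable,
    focal: str,
    n_boot: int = 100,
    train_fraction: float = 0.5,
    seed: int = 0,
) -> BaselineReport:
    """Bootstrapped unpenalized logistic baselines around one focal region.

    Distinguishes "this region predicts phenotype" from "global construct
    expression predicts phenotype": if the focal region merely proxies the
    brain-wide average, the average-signal model matches it; if the region
    carries its own information, the focal model wins and adding the average
    does not improve it.
    """
    if focal not in m.regions:
        raise UnknownRegionError(f"unknown focal region {focal!r}")
    X, yy = _design(m, y)
    yi = yy.astype(int)
    avg = X.mean(axis=1)
    foc = m.column(focal)
    sets = {
        "brain_average": avg[:, None],
        "focal": foc[:, None],
        "both": np.column_stack([foc, avg]),
    }
    child_seeds = np.random.SeedSequence(seed).generate_state(n_boot) % (2**31 - 1)
    accs = {name: np.empty(n_boot) for name in sets}
    for b in range(n_boot):
        tr, te = _stratified_split(yi, train_fraction, int(child_seeds[b]))
        for name, Z in sets.items():
            mu = Z[tr].mean(axis=0)
            sd = Z[tr].std(axis=0, ddof=0)
            sd = np.where(sd == 0, 1.0, sd)
            b0, bb = _glm.fit_logistic_mle((Z[tr] - mu) / sd, yy[tr])
            eta = b0 + ((Z[te] - mu) / sd) @ bb
            accs[name][b] = float(np.mean((eta > 0).astype(int) == yi[te]))
    return BaselineReport(focal=focal, n_boot=n_boot, rng_seed=seed, accuracies=accs)
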