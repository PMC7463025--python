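"""Ensemble species distribution modelling core.

:class:`EnsembleSDM` is the model object: a presence/absence feature
table plus a panel of six classification algorithms (GAM, GBM, CTA, FDA,
RF, MAXENT). ``fit()`` runs repeated 75/25 calibration/testing splits
(default 10, giving 60 fitted models), scores every fit by the area under
the ROC curve (AUC) on its held-out quarter, measures permutation
variable importance, and returns an :class:`EnsembleSDMResults` whose
ensemble prediction is the AUC-weighted average of all fits with test
AUC > 0.5.

Algorithm realisations (binomial response, logit link where applicable):

* GAM — penalised logistic regression on cubic B-spline bases;
* GBM — gradient-boosted classification trees;
* CTA — a single classification tree;
* FDA — linear discriminant analysis on a piecewise-linear spline basis;
* RF — random forest;
* MAXENT — ridge-penalised logistic regression on linear + quadratic +
  hinge feature expansions (the presence/absence reduction of maximum
  entropy modelling).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.compose import ColumnTransformer
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import FeatureUnion, Pipeline
from sklearn.preprocessing import (
    OneHotEncoder,
    PolynomialFeatures,
    SplineTransformer,
    StandardScaler,
)
from sklearn.tree import DecisionTreeClassifier

logger = logging.getLogger(__name__)

ALGORITHMS = ("GAM", "GBM", "CTA", "FDA", "RF", "MAXENT")

__all__ = [
    "ALGORITHMS",
    "CVConfig",
    "ModelRun",
    "EnsembleSurface",
    "EnsembleSDM",
    "EnsembleSDMResults",
    "NoSkillfulModelsError",
    "split_calibration",
    "fit_single",
    "auc",
    "variable_importance",
    "run_cross_validation",
    "build_importance_table",
    "ensemble_predict",
]


class NoSkillfulModelsError(RuntimeError):
    """No fitted model exceeded chance-level test AUC."""


@dataclass(frozen=True)
class CVConfig:
    """Repeated-split cross-validation settings."""

    calib_fraction: float = 0.75
    n_runs: int = 10
    seed: int = 0
    algorithms: tuple = ALGORITHMS
    n_importance_perm: int = 10

    def __post_init__(self):
        if not (0 < self.calib_fraction < 1):
            raise ValueError("calib_fraction must lie in (0, 1)")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if not self.algorithms:
            raise ValueError("algorithms must be non-empty")
        unknown = set(self.algorithms) - set(ALGORITHMS)
        if unknown:
            raise ValueError(f"unknown algorithms: {sorted(unknown)}")

    def split_seed(self, run_index: int) -> int:
        """Deterministic per-run seed (documented counter scheme)."""
        return (self.seed * 100_003 + run_index) % (2**31)


@dataclass
class ModelRun:
    """One algorithm fitted on one calibration split."""

    algorithm: str
    run_index: int
    split_seed: int
    auc_test: float
    importance: dict
    model: "FittedModel"


@dataclass
class EnsembleSurface:
    """AUC-weighted ensemble occurrence probability per cell."""

    probability: np.ndarray
    cell_ids: np.ndarray | None
    weights: dict  # (algorithm, run_index) -> weight, sums to 1
    auc_ensemble: float | None = None


# ---------------------------------------------------------------------------
# algorithm factory
# ---------------------------------------------------------------------------


def _onehot():
    return OneHotEncoder(handle_unknown="ignore", sparse_output=False)


def _make_estimator(algorithm, continuous, categorical, random_state):
    cat = ("cat", _onehot(), list(categorical))
    cont = list(continuous)
    if algorithm == "GAM":
        pre = ColumnTransformer(
            [("spline", SplineTransformer(n_knots=5, degree=3, knots="uniform"), cont), cat]
        )
        clf = LogisticRegression(C=10.0, max_iter=5_000)
    elif algorithm == "GBM":
        pre = ColumnTransformer([("num", "passthrough", cont), cat])
        clf = GradientBoostingClassifier(
            n_estimators=100, learning_rate=0.1, max_depth=3, random_state=random_state
        )
    elif algorithm == "CTA":
        pre = ColumnTransformer([("num", "passthrough", cont), cat])
        clf = DecisionTreeClassifier(
            max_depth=6, min_samples_leaf=8, random_state=random_state
        )
    elif algorithm == "FDA":
        pre = ColumnTransformer(
            [("hinge", SplineTransformer(n_knots=4, degree=1, knots="uniform"), cont), cat]
        )
        clf = LinearDiscriminantAnalysis()
    elif algorithm == "RF":
        pre = ColumnTransformer([("num", "passthrough", cont), cat])
        clf = RandomForestClassifier(
            n_estimators=100, min_samples_leaf=5, random_state=random_state
        )
    elif algorithm == "MAXENT":
        expand = FeatureUnion(
            [
                ("poly", PolynomialFeatures(degree=2, include_bias=False)),
                ("hinge", SplineTransformer(n_knots=6, degree=1, knots="uniform")),
            ]
        )
        pre = ColumnTransformer(
            [("maxent", Pipeline([("expand", expand), ("scale", StandardScaler())]), cont), cat]
        )
        clf = LogisticRegression(C=1.0, max_iter=5_000)
    else:  # pragma: no cover - guarded by CVConfig
        raise ValueError(f"unknown algorithm {algorithm!r}")
    return Pipeline([("pre", pre), ("clf", clf)])


def _fallback_estimator(continuous, categorical):
    pre = ColumnTransformer(
        [("num", StandardScaler(), list(continuous)), ("cat", _onehot(), list(categorical))]
    )
    return Pipeline([("pre", pre), ("clf", LogisticRegression(C=1.0, max_iter=2_000))])


@dataclass
class FittedModel:
    """A fitted probability-emitting classifier over named predictors."""

    algorithm: str
    predictors: list
    estimator: object

    def predict_prob(self, rows: pd.DataFrame) -> np.ndarray:
        X = rows[self.predictors]
        proba = self.estimator.predict_proba(X)
        classes = list(self.estimator.classes_)
        return proba[:, classes.index(1)]


def _split_columns(table: pd.DataFrame, predictors):
    num = table[predictors].select_dtypes(include=[np.number]).columns
    continuous = [p for p in predictors if p in num]
    categorical = [p for p in predictors if p not in num]
    return continuous, categorical


def fit_single(
    algorithm: str,
    calibration: pd.DataFrame,
    predictors,
    response_col: str = "response",
    random_state: int = 0,
) -> FittedModel:
    """Fit one algorithm on a calibration table.

    On failure the model is retried with a documented fallback
    (standardised ridge logistic regression); a second failure propagates.
    """
    y = calibration[response_col].to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("calibration data must contain both classes")
    continuous, categorical = _split_columns(calibration, predictors)
    X = calibration[list(predictors)]
    est = _make_estimator(algorithm, continuous, categorical, random_state)
    try:
        est.fit(X, y)
    except Exception as exc:  # noqa: BLE001 - any base-learner failure
        logger.warning("%s fit failed (%s); retrying with fallback", algorithm, exc)
        est = _fallback_estimator(continuous, categorical)
        est.fit(X, y)
    return FittedModel(algorithm=algorithm, predictors=list(predictors), estimator=est)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


def auc(scores, labels) -> float:
    """Area under the ROC curve as the rank-sum concordance statistic.

    Equals the probability that a random presence outranks a random
    absence; ties count one half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("labels must contain both classes")
    ranks = rankdata(scores)
    rank_sum = ranks[labels == 1].sum()
    return float((rank_sum - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def split_calibration(table: pd.DataFrame, config: CVConfig, run_index: int):
    """Stratified 75/25 calibration/test split, deterministic per run."""
    y = table["response"].to_numpy(dtype=int)
    if len(table) < 8 or len(np.unique(y)) < 2:
        raise ValueError("need >= 8 rows with both classes")
    rng = np.random.default_rng(config.split_seed(run_index))
    classes = np.unique(y)
    sizes = {cls: int((y == cls).sum()) for cls in classes}
    if min(sizes.values()) < 2:
        raise ValueError("every class needs at least 2 rows")
    # largest-remainder allocation keeps the overall split exactly 75/25
    # while each class stays balanced within one row
    exact = {cls: config.calib_fraction * n for cls, n in sizes.items()}
    n_cal = {cls: int(np.floor(v)) for cls, v in exact.items()}
    short = int(round(config.calib_fraction * len(y))) - sum(n_cal.values())
    for cls in sorted(classes, key=lambda c: exact[c] - n_cal[c], reverse=True)[:short]:
        n_cal[cls] += 1
    calib_idx = []
    test_idx = []
    for cls in classes:
        idx = np.flatnonzero(y == cls)
        perm = rng.permutation(idx)
        k = min(max(n_cal[cls], 1), len(idx) - 1)
        calib_idx.extend(perm[:k])
        test_idx.extend(perm[k:])
    return table.iloc[np.sort(calib_idx)], table.iloc[np.sort(test_idx)]


def variable_importance(
    model: FittedModel,
    rows: pd.DataFrame,
    n_perm: int = 10,
    seed: int = 0,
    variables=None,
) -> dict:
    """Permutation importance: 1 - mean Pearson r between the standard
    predictions and predictions with one variable shuffled, clipped to
    [0, 1] (the biomod2-style zero-to-one ranking)."""
    variables = list(variables) if variables is not None else list(model.predictors)
    base = model.predict_prob(rows)
    rng = np.random.default_rng(seed)
    if np.std(base) == 0:
        logger.warning("constant predictions; all importances set to 0")
        return {v: 0.0 for v in variables}
    out = {}
    for v in variables:
        rs = []
        for _ in range(n_perm):
            shuffled = rows.copy()
            shuffled[v] = rng.permutation(shuffled[v].to_numpy())
            pred = model.predict_prob(shuffled)
            if np.std(pred) == 0:
                rs.append(0.0)  # permutation flattened the response surface
            else:
                rs.append(float(np.corrcoef(base, pred)[0, 1]))
        out[v] = float(np.clip(1.0 - np.mean(rs), 0.0, 1.0))
    return out


def run_cross_validation(
    table: pd.DataFrame,
    config: CVConfig,
    predictors=None,
    response_col: str = "response",
) -> list:
    """Fit every algorithm on every calibration split.

    Returns ``|algorithms| x n_runs`` :class:`ModelRun` objects minus
    logged failures; aborts if more than 20 % of runs fail.
    """
    if predictors is None:
        predictors = [
            c for c in table.columns if c not in (response_col, "effort_m", "cell_id")
        ]
    runs = []
    failures = 0
    total = len(config.algorithms) * config.n_runs
    for run_index in range(1, config.n_runs + 1):
        split_seed = config.split_seed(run_index)
        calib, test = split_calibration(table, config, run_index)
        for ai, algorithm in enumerate(config.algorithms):
            try:
                model = fit_single(
                    algorithm, calib, predictors, response_col,
                    random_state=(split_seed + ai) % (2**31),
                )
                auc_test = auc(model.predict_prob(test), test[response_col])
                importance = variable_importance(
                    model, calib,
                    n_perm=config.n_importance_perm,
                    seed=(split_seed + 7919 * (ai + 1)) % (2**31),
                )
            except Exception as exc:  # noqa: BLE001
                failures += 1
                logger.warning("run %d %s failed: %s", run_index, algorithm, exc)
                continue
            runs.append(
                ModelRun(algorithm, run_index, split_seed, auc_test, importance, model)
            )
    if failures > 0.2 * total:
        raise RuntimeError(f"{failures}/{total} model runs failed; aborting")
    return runs


def build_importance_table(runs) -> pd.DataFrame:
    """Per-algorithm mean importance over runs plus a mean-of-means row."""
    if not runs:
        raise ValueError("runs must be non-empty")
    variables = list(runs[0].importance.keys())
    algorithms = list(dict.fromkeys(r.algorithm for r in runs))
    rows = {}
    for algorithm in algorithms:
        imps = [r.importance for r in runs if r.algorithm == algorithm]
        rows[algorithm] = [float(np.mean([d[v] for d in imps])) for v in variables]
    table = pd.DataFrame.from_dict(rows, orient="index", columns=variables)
    table.loc["Mean of means"] = table.loc[algorithms].mean(axis=0)
    return table


def ensemble_predict(runs, features: pd.DataFrame) -> EnsembleSurface:
    """AUC-weighted average prediction over included model runs.

    Runs with test AUC <= 0.5 (chance or worse) are excluded; weights are
    proportional to test AUC and sum to 1.
    """
    included = [r for r in runs if r.auc_test > 0.5]
    if not included:
        raise NoSkillfulModelsError("no skillful models (all test AUC <= 0.5)")
    total = sum(r.auc_test for r in included)
    weights = {(r.algorithm, r.run_index): r.auc_test / total for r in included}
    prob = np.zeros(len(features))
    for r in included:
        prob += weights[(r.algorithm, r.run_index)] * r.model.predict_prob(features)
    cell_ids = features["cell_id"].to_numpy() if "cell_id" in features else None
    return EnsembleSurface(probability=prob, cell_ids=cell_ids, weights=weights)


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------


class EnsembleSDM:
    """Ensemble species distribution model over a feature table.

    Parameters
    ----------
    table : DataFrame
        One row per presence/absence cell; a binary ``response`` column
        plus predictor columns (``effort_m`` and ``cell_id`` are ignored
        as predictors if present).
    predictors : list of str, optional
        Predictor columns; defaults to everything except bookkeeping.
    algorithms : sequence of str
        Subset of :data:`ALGORITHMS`.
    """

    def __init__(self, table, predictors=None, response_col="response",
                 algorithms=ALGORITHMS):
        if response_col not in table.columns:
            raise ValueError(f"table lacks response column {response_col!r}")
        self.table = table.reset_index(drop=True)
        self.response_col = response_col
        if predictors is None:
            predictors = [
                c for c in table.columns if c not in (response_col, "effort_m", "cell_id")
            ]
        self.predictors = list(predictors)
        self.algorithms = tuple(algorithms)

    @classmethod
    def from_feature_table(cls, table, **kwargs):
        """Construct from an assembled presence/absence feature table."""
        return cls(table, **kwargs)

    def fit(self, n_runs=10, calib_fraction=0.75, seed=0, n_importance_perm=10):
        """Run the repeated-split ensemble and return results."""
        config = CVConfig(
            calib_fraction=calib_fraction,
            n_runs=n_runs,
            seed=seed,
            algorithms=self.algorithms,
            n_importance_perm=n_importance_perm,
        )
        runs = run_cross_validation(
            self.table, config, predictors=self.predictors,
            response_col=self.response_col,
        )
        return EnsembleSDMResults(self, config, runs)


class EnsembleSDMResults:
    """Fitted ensemble: per-run AUCs, importances, weights, predictions."""

    def __init__(self, model: EnsembleSDM, config: CVConfig, runs):
        self.model = model
        self.config = config
        self.runs = runs
        self._ensemble_auc = None

    # -- evaluation --------------------------------------------------------

    @property
    def auc_table(self) -> pd.DataFrame:
        """Test AUC per (run, algorithm)."""
        df = pd.DataFrame(
            [(r.run_index, r.algorithm, r.auc_test) for r in self.runs],
            columns=["run", "algorithm", "auc"],
        )
        return df.pivot(index="run", columns="algorithm", values="auc")

    @property
    def median_single_auc(self) -> float:
        return float(np.median([r.auc_test for r in self.runs]))

    @property
    def ensemble_auc(self) -> float:
        """Held-out AUC of the ensemble.

        For each split, the models calibrated on that split (test AUC
        > 0.5) are AUC-weight-averaged and scored on the split's test
        quarter; the per-split AUCs are averaged.
        """
        if self._ensemble_auc is None:
            per_run = []
            for run_index in range(1, self.config.n_runs + 1):
                members = [
                    r for r in self.runs
                    if r.run_index == run_index and r.auc_test > 0.5
                ]
                if not members:
                    continue
                _, test = split_calibration(self.model.table, self.config, run_index)
                total = sum(r.auc_test for r in members)
                pred = np.zeros(len(test))
                for r in members:
                    pred += (r.auc_test / total) * r.model.predict_prob(test)
                per_run.append(auc(pred, test[self.model.response_col]))
            if not per_run:
                raise NoSkillfulModelsError("no skillful models in any run")
            self._ensemble_auc = float(np.mean(per_run))
        return self._ensemble_auc

    @property
    def importance_table(self) -> pd.DataFrame:
        return build_importance_table(self.runs)

    # -- prediction --------------------------------------------------------

    def predict(self, features: pd.DataFrame) -> EnsembleSurface:
        """Ensemble surface over arbitrary cells (full grid included)."""
        surface = ensemble_predict(self.runs, features)
        surface.auc_ensemble = self.ensemble_auc
        return surface

    def predict_grid(self, grid, features: pd.DataFrame):
        """(surface, grid-shaped probability array with NaN off-marine)."""
        surface = self.predict(features)
        prob = np.full((grid.n_rows, grid.n_cols), np.nan)
        rows, cols = grid.rowcol(surface.cell_ids)
        prob[rows, cols] = surface.probability
        return surface, prob

    # -- reporting ---------------------------------------------------------

    def summary(self) -> str:
        """Plain-text summary table of the fitted ensemble."""
        at = self.auc_table
        lines = [
            "Ensemble species distribution model",
            "=" * 60,
            f"rows: {len(self.model.table)}   predictors: {len(self.model.predictors)}"
            f"   runs: {self.config.n_runs} x {len(self.config.algorithms)} algorithms",
            "",
            "Test AUC by algorithm (mean +/- sd over runs):",
        ]
        for algorithm in self.config.algorithms:
            if algorithm in at.columns:
                vals = at[algorithm].dropna()
                lines.append(
                    f"  {algorithm:<8} {vals.mean():.3f} +/- {vals.std(ddof=0):.3f}"
                )
        lines += [
            f"  median single-model AUC: {self.median_single_auc:.3f}",
            f"  ensemble AUC:            {self.ensemble_auc:.3f}",
            "",
            "Variable importance (mean of means):",
        ]
        mom = self.importance_table.loc["Mean of means"].sort_values(ascending=False)
        for name, value in mom.items():
            lines.append(f"  {name:<16} {value:.3f}")
        return "\n".join(lines)
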