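"""Grouped cross-validation with in-fold feature screening and tree models.

All records sharing a (cell line, compound) pair — i.e. one dose-response
curve — travel together through cross-validation so that no curve leaks
between training and test.  Feature screening (Pearson correlation against
the response) is recomputed inside each training fold before the model is
fit, and out-of-fold predictions are pooled for global and per-subgroup
metrics.

R^2 is the squared Pearson correlation of predictions with observations by
default (``r2_mode="pearson"``); the coefficient-of-determination variant
is available as ``r2_mode="cod"``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from sklearn.ensemble import HistGradientBoostingRegressor, RandomForestRegressor
from sklearn.inspection import permutation_importance
from sklearn.linear_model import LinearRegression

from .features import (KEY_COLS, RESPONSE_COL, correlate_features,
                       feature_columns, pick_max_variance_dose,
                       rank_and_select)

logger = logging.getLogger(__name__)

MODEL_FAMILIES = ("baseline_dose", "linear", "random_forest",
                  "gradient_boosting")
DOSE_COL = "log10_dose"


@dataclass(frozen=True)
class ModelSpec:
    """One model configuration: family, feature budget, hyperparameters."""

    family: str = "random_forest"
    n_features: int = 500
    trees: int = 500
    predictors_per_split: int | None = None
    min_node_size: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in MODEL_FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}")
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")


@dataclass(frozen=True)
class FoldAssignment:
    """Mapping (cell line, compound) -> fold index in 1..K."""

    mapping: dict[tuple[str, str], int]
    n_folds: int
    seed: int

    def fold_of(self, table: pd.DataFrame) -> np.ndarray:
        keys = list(zip(table["cell_line"], table["compound"]))
        return np.array([self.mapping[k] for k in keys], dtype=int)


@dataclass
class ModelResult:
    """Out-of-fold predictions plus pooled metrics and fold selections."""

    predictions: pd.DataFrame       # KEY_COLS + observed, predicted, fold
    r2: float
    rmse: float
    fold_selections: list[list[str]]
    spec: ModelSpec
    r2_mode: str = "pearson"
    fitted_models: list = field(default_factory=list, repr=False)


def make_group_folds(combinations, n_folds: int = 10,
                     seed: int = 0) -> FoldAssignment:
    """Random balanced partition of (cell line, compound) combinations.

    Fold sizes differ by at most one combination; deterministic given seed.
    """
    combos = [tuple(c) for c in combinations]
    if len(set(combos)) != len(combos):
        raise ValueError("duplicate combinations in fold input")
    if n_folds > len(combos):
        raise ValueError(f"cannot make {n_folds} folds from {len(combos)} "
                         "combinations")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(combos))
    mapping: dict[tuple[str, str], int] = {}
    for fold_idx, chunk in enumerate(np.array_split(order, n_folds), start=1):
        for i in chunk:
            mapping[combos[i]] = fold_idx
    return FoldAssignment(mapping, n_folds, seed)


class DoseOnlyBaseline:
    """Feature-free benchmark: training-set mean viability per concentration."""

    def __init__(self) -> None:
        self.means_: dict[float, float] = {}

    def fit(self, concentrations, y) -> "DoseOnlyBaseline":
        s = pd.Series(np.asarray(y, dtype=float),
                      index=np.asarray(concentrations, dtype=float))
        self.means_ = s.groupby(level=0).mean().to_dict()
        return self

    def predict(self, concentrations) -> np.ndarray:
        out = []
        for x in np.asarray(concentrations, dtype=float):
            if x not in self.means_:
                raise ValueError(f"concentration {x} unseen during training")
            out.append(self.means_[x])
        return np.asarray(out)


def evaluate(predictions, observed, r2_mode: str = "pearson"
             ) -> tuple[float, float]:
    """(R^2, RMSE) of a prediction vector against observations.

    ``pearson`` R^2 is the squared Pearson correlation (shift/scale
    invariant); ``cod`` is 1 - SS_res/SS_tot.  Zero-variance predictions
    get R^2 = 0 with a warning.
    """
    p = np.asarray(predictions, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape or p.size < 2:
        raise ValueError("predictions and observations must share length >= 2")
    rmse = float(np.sqrt(np.mean((p - o) ** 2)))
    if r2_mode == "pearson":
        if p.std() == 0 or o.std() == 0:
            warnings.warn("zero-variance vector; R^2 set to 0", stacklevel=2)
            return 0.0, rmse
        r = float(np.corrcoef(p, o)[0, 1])
        return r * r, rmse
    if r2_mode == "cod":
        ss_tot = float(np.sum((o - o.mean()) ** 2))
        if ss_tot == 0:
            warnings.warn("zero-variance observations; R^2 set to 0",
                          stacklevel=2)
            return 0.0, rmse
        return 1.0 - float(np.sum((p - o) ** 2)) / ss_tot, rmse
    raise ValueError(f"unknown r2_mode {r2_mode!r}")


def _build_estimator(spec: ModelSpec, n_features: int):
    if spec.family == "linear":
        return LinearRegression()
    if spec.family == "random_forest":
        mtry = spec.predictors_per_split
        if mtry is None:
            mtry = 22  # the screen's default for the 500-tree model
        if mtry > n_features:
            mtry = max(1, int(np.floor(np.sqrt(n_features))))
        return RandomForestRegressor(
            n_estimators=spec.trees, max_features=mtry,
            min_samples_leaf=spec.min_node_size,
            random_state=spec.seed, n_jobs=1)
    if spec.family == "gradient_boosting":
        return HistGradientBoostingRegressor(
            min_samples_leaf=max(spec.min_node_size, 2),
            random_state=spec.seed)
    raise ValueError(f"family {spec.family!r} has no estimator")


def _design(table: pd.DataFrame, selected: list[str],
            include_dose: bool) -> np.ndarray:
    cols = [table[selected].to_numpy(dtype=float)] if selected else []
    if include_dose:
        cols.append(np.log10(
            table["concentration"].to_numpy(dtype=float))[:, None])
    if not cols:
        raise ValueError("empty design: no features and no dose covariate")
    return np.hstack(cols)


def cross_validate(
    table: pd.DataFrame,
    spec: ModelSpec,
    folds: FoldAssignment,
    include_dose: bool = True,
    signed_ranking: bool = False,
    r2_mode: str = "pearson",
    keep_models: bool = False,
) -> ModelResult:
    """Grouped CV with per-fold correlation screening.

    For each fold: Pearson correlations are recomputed on the training rows
    only, the top ``spec.n_features`` features are selected, the model is
    fit and the held-out rows predicted.  Out-of-fold predictions are
    pooled for the reported metrics.
    """
    table = table.reset_index(drop=True)
    fold_of = folds.fold_of(table)
    feats = feature_columns(table)
    preds = np.full(len(table), np.nan)
    fold_selections: list[list[str]] = []
    models = []
    for fold in range(1, folds.n_folds + 1):
        test_mask = fold_of == fold
        train = table.loc[~test_mask]
        test = table.loc[test_mask]
        if test.empty:
            fold_selections.append([])
            continue
        if spec.family == "baseline_dose":
            model = DoseOnlyBaseline().fit(train["concentration"],
                                           train[RESPONSE_COL])
            preds[test_mask] = model.predict(test["concentration"])
            fold_selections.append([])
        else:
            ranking = correlate_features(train)
            k = min(spec.n_features, len(feats))
            selected = rank_and_select(ranking, k, signed=signed_ranking)
            fold_selections.append(selected)
            est = _build_estimator(spec, k + int(include_dose))
            est.fit(_design(train, selected, include_dose),
                    train[RESPONSE_COL].to_numpy(dtype=float))
            preds[test_mask] = est.predict(_design(test, selected,
                                                   include_dose))
            model = est
        if keep_models:
            models.append(model)
    if np.isnan(preds).any():
        raise AssertionError("some rows never received an OOF prediction")
    out = table[KEY_COLS].copy()
    out["observed"] = table[RESPONSE_COL].to_numpy(dtype=float)
    out["predicted"] = preds
    out["fold"] = fold_of
    r2, rmse = evaluate(preds, out["observed"], r2_mode=r2_mode)
    return ModelResult(out, r2, rmse, fold_selections, spec, r2_mode, models)


def subset_metrics(result: ModelResult, by: str) -> pd.DataFrame:
    """Recompute (R^2, RMSE) per compound or per cell line.

    Groups with fewer than 3 rows are flagged and excluded.
    """
    if by not in ("compound", "cell_line"):
        raise ValueError("by must be 'compound' or 'cell_line'")
    rows = []
    for key, grp in result.predictions.groupby(by):
        if len(grp) < 3:
            logger.info("group %s has <3 rows; excluded from subset metrics",
                        key)
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r2, rmse = evaluate(grp["predicted"], grp["observed"],
                                r2_mode=result.r2_mode)
        rows.append((key, len(grp), r2, rmse))
    return pd.DataFrame(rows, columns=[by, "n", "r2", "rmse"])


def hyperparameter_sweep(
    table: pd.DataFrame,
    folds: FoldAssignment,
    grid: dict[str, list] | None = None,
    base_spec: ModelSpec | None = None,
    **cv_kwargs,
) -> pd.DataFrame:
    """Cross-validated metrics over the random-forest tuning grid.

    The default grid is the standard tuning sweep: trees {500, 1000, 1500,
    2000}, predictors per split {11, 22, 33, 44}, minimal node size
    {3, 5, 10}; pass a partial ``grid`` to sweep a subset.  All points use
    identical folds.
    """
    base = base_spec or ModelSpec(family="random_forest")
    full = {"trees": [500, 1000, 1500, 2000],
            "predictors_per_split": [11, 22, 33, 44],
            "min_node_size": [3, 5, 10]}
    grid = {**{k: [getattr(base, k)] for k in full}, **(grid or {})}
    rows = []
    for trees, mtry, node in product(grid["trees"],
                                     grid["predictors_per_split"],
                                     grid["min_node_size"]):
        spec = ModelSpec(family="random_forest", n_features=base.n_features,
                         trees=trees, predictors_per_split=mtry,
                         min_node_size=node, seed=base.seed)
        res = cross_validate(table, spec, folds, **cv_kwargs)
        rows.append((trees, mtry, node, res.r2, res.rmse))
    return pd.DataFrame(rows, columns=["trees", "predictors_per_split",
                                       "min_node_size", "r2", "rmse"])


def importance(
    model,
    feature_names: list[str],
    annotation: pd.DataFrame | None = None,
    mode: str = "impurity",
    X=None,
    y=None,
    n_repeats: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Ranked variable importances with kinase-class tags.

    ``mode='impurity'`` reads the ensemble's impurity importances;
    ``mode='permutation'`` permutes columns of (X, y).  Inhibition features
    are tagged via the kinase annotation (dark/light/non-kinase; proteins
    missing from the annotation default to non-kinase with a warning);
    expression features are tagged "expression".
    """
    if mode == "impurity":
        if not hasattr(model, "feature_importances_"):
            raise ValueError("model family does not expose impurity "
                             "importances")
        scores = np.asarray(model.feature_importances_)
    elif mode == "permutation":
        if X is None or y is None:
            raise ValueError("permutation importance requires X and y")
        if not hasattr(model, "predict"):
            raise ValueError("model family does not support importance")
        res = permutation_importance(model, X, y, n_repeats=n_repeats,
                                     random_state=seed)
        scores = res.importances_mean
    else:
        raise ValueError(f"unknown importance mode {mode!r}")
    if len(scores) != len(feature_names):
        raise ValueError("feature_names length does not match model input")

    ann = {}
    if annotation is not None:
        ann = dict(zip(annotation["protein"], annotation["class"]))

    def tag(name: str) -> str:
        if name.startswith("act_"):
            prot = name[len("act_"):]
            if prot not in ann:
                if annotation is not None:
                    warnings.warn(f"protein {prot!r} missing from annotation; "
                                  "tagged non-kinase", stacklevel=2)
                return "non-kinase"
            cls = ann[prot]
            return {"dark": "dark kinase", "light": "light kinase"}.get(cls,
                                                                        cls)
        if name.startswith("exp_"):
            return "expression"
        return "other"

    df = pd.DataFrame({"feature": feature_names, "importance": scores,
                       "tag": [tag(f) for f in feature_names]})
    df = df.sort_values(["importance", "feature"], ascending=[False, True],
                        kind="mergesort").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def planted_importance_rank_test(importance_df: pd.DataFrame,
                                 planted: set[str]) -> float:
    """One-sided Mann-Whitney p-value that planted inhibition features rank
    better (lower rank number) than non-planted inhibition features."""
    act = importance_df[importance_df["feature"].str.startswith("act_")]
    planted_ranks = act.loc[act["feature"].isin(planted), "rank"]
    other_ranks = act.loc[~act["feature"].isin(planted), "rank"]
    if planted_ranks.empty or other_ranks.empty:
        raise ValueError("need both planted and non-planted inhibition "
                         "features")
    return float(mannwhitneyu(planted_ranks, other_ranks,
                              alternative="less").pvalue)


def ablation_run(
    table: pd.DataFrame,
    folds: FoldAssignment,
    configs: list[dict],
    annotation: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Cross-validated metrics per feature-set configuration.

    Each config dict may set: ``classes`` (tuple of class names among
    inhibition/expression/cnv/proteomics/dependency), ``kinase_only``
    (restrict inhibition columns to annotated kinases), ``single_dose``
    (keep only the max-variance dose per compound), and ``k`` (feature
    budget).  The dose covariate accompanies the inhibition class; models
    without inhibition features see no dose information, so their score
    reflects dose-invariant features alone.
    """
    prefix_of = {"inhibition": "act_", "expression": "exp_", "cnv": "cnv_",
                 "proteomics": "prot_", "dependency": "dep_"}
    rows = []
    for cfg in configs:
        classes = tuple(cfg.get("classes", ("inhibition", "expression")))
        unknown = [c for c in classes if c not in prefix_of]
        if unknown:
            raise ValueError(f"unknown classes {unknown}")
        keep_prefixes = tuple(prefix_of[c] for c in classes)
        feats = [f for f in feature_columns(table)
                 if f.startswith(keep_prefixes)]
        if cfg.get("kinase_only") and "inhibition" in classes:
            if annotation is None:
                raise ValueError("kinase_only requires an annotation table")
            kinases = set(annotation.loc[annotation["class"]
                                         .isin(["dark", "light"]), "protein"])
            feats = [f for f in feats
                     if not f.startswith("act_") or f[len("act_"):] in kinases]
        if not feats:
            raise ValueError(f"config {cfg} leaves an empty feature set")
        sub = table[KEY_COLS + [RESPONSE_COL] + feats]
        if cfg.get("single_dose"):
            best_dose = pick_max_variance_dose(sub)
            mask = [best_dose.get(c) == x for c, x in
                    zip(sub["compound"], sub["concentration"])]
            sub = sub.loc[mask]
        include_dose = "inhibition" in classes
        k = min(cfg.get("k", 500), len(feats))
        spec = ModelSpec(family=cfg.get("family", "random_forest"),
                         n_features=k, trees=cfg.get("trees", 500),
                         seed=cfg.get("seed", 0))
        res = cross_validate(sub, spec, folds, include_dose=include_dose)
        rows.append(("+".join(classes), bool(cfg.get("kinase_only")),
                     bool(cfg.get("single_dose")), k, res.r2, res.rmse))
    return pd.DataFrame(rows, columns=["classes", "kinase_only",
                                       "single_dose", "k", "r2", "rmse"])
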