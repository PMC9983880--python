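"""Final-model fitting, prediction of untested combinations, and
comparison against plate-based viability measurements.

The final model is fit on the full assembled table (correlation screening
on all rows, then the top-k features).  Predictions are produced for every
(cell line, compound) pair that has expression and an inhibition profile
but no viability screen, at all grid concentrations.  Laboratory plates
are normalized row-wise to their DMSO-only controls, filtered by a <120%
of-DMSO quality check, and compared to predictions by R^2/RMSE.
"""

from __future__ import annotations

import hashlib
import logging
import pickle
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import (KEY_COLS, RESPONSE_COL, correlate_features,
                       feature_columns, rank_and_select)
from .modeling import ModelSpec, _build_estimator, _design, evaluate
from .preprocess import InhibitionProfile

logger = logging.getLogger(__name__)


@dataclass
class FinalModel:
    """Fitted full-data model plus everything needed to reuse it."""

    model: object
    selected_features: list[str]
    ranking: pd.DataFrame
    spec: ModelSpec
    include_dose: bool
    dose_grid: np.ndarray

    @property
    def feature_hash(self) -> str:
        return hashlib.sha256(
            "\n".join(self.selected_features).encode()).hexdigest()[:16]

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        return self.model.predict(
            _design(table, self.selected_features, self.include_dose))

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @classmethod
    def load(cls, path) -> "FinalModel":
        with open(path, "rb") as fh:
            return pickle.load(fh)


def fit_final_model(
    table: pd.DataFrame,
    k: int = 500,
    spec: ModelSpec | None = None,
    include_dose: bool = True,
    signed_ranking: bool = False,
) -> FinalModel:
    """Correlation-screen on all rows, select top-k, fit, package."""
    spec = spec or ModelSpec(family="random_forest", n_features=k)
    feats = feature_columns(table)
    if k > len(feats):
        raise ValueError(f"k={k} exceeds available feature count {len(feats)}")
    ranking = correlate_features(table)
    selected = rank_and_select(ranking, k, signed=signed_ranking)
    est = _build_estimator(spec, k + int(include_dose))
    est.fit(_design(table, selected, include_dose),
            table[RESPONSE_COL].to_numpy(dtype=float))
    grid = np.sort(table["concentration"].unique())
    return FinalModel(est, selected, ranking, spec, include_dose, grid)


def predict_untested(
    final: FinalModel,
    expression: pd.DataFrame,
    profile: InhibitionProfile,
    tested_mask: set[tuple[str, str]],
) -> pd.DataFrame:
    """Predicted viability curves for every untested (cell line, compound).

    Cell lines come from the expression index, compounds from the
    inhibition profile; pairs in ``tested_mask`` are excluded, pairs
    missing inputs are skipped and listed in ``attrs['skipped']``.
    Returns a long DataFrame (cell_line, compound, concentration,
    predicted) with provenance in ``attrs``.
    """
    lines = list(expression.index)
    compounds = list(profile.compounds)
    act = profile.to_frame()
    needed_exp = [f for f in final.selected_features if f.startswith("exp_")]
    missing_cols = [c for c in needed_exp if c not in expression.columns]
    skipped = []
    if missing_cols:
        raise ValueError(f"expression matrix lacks selected features: "
                         f"{missing_cols[:5]}")
    rows = []
    for line in lines:
        for cmpd in compounds:
            if (line, cmpd) in tested_mask:
                continue
            rows.append((line, cmpd))
    if not rows:
        out = pd.DataFrame(columns=["cell_line", "compound", "concentration",
                                    "predicted"])
        out.attrs["skipped"] = skipped
        return out
    combos = pd.DataFrame(rows, columns=["cell_line", "compound"])
    grid = pd.DataFrame({"concentration": final.dose_grid})
    full = combos.merge(grid, how="cross")
    full = full.merge(act, on=["compound", "concentration"], how="left")
    if full.filter(like="act_").isna().any().any():
        bad = full.loc[full.filter(like="act_").isna().any(axis=1),
                       ["cell_line", "compound"]].drop_duplicates()
        skipped.extend(map(tuple, bad.to_numpy()))
        full = full.dropna()
    exp_block = expression.loc[full["cell_line"]]
    for col in needed_exp:
        full[col] = exp_block[col].to_numpy()
    full["predicted"] = final.predict(full)
    out = full[["cell_line", "compound", "concentration", "predicted"]]
    out = out.reset_index(drop=True)
    out.attrs["skipped"] = skipped
    out.attrs["provenance"] = {"feature_hash": final.feature_hash,
                               "model_seed": final.spec.seed,
                               "n_features": len(final.selected_features)}
    return out


def normalize_plate(measurements: pd.DataFrame
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Row-wise DMSO normalization of raw plate luminescence.

    ``measurements`` columns: row_id, cell_line, compound, concentration,
    replicate, signal, is_control.  Each treated signal is divided by the
    mean DMSO-control signal of its plate row; replicates are averaged
    after normalization.  Rows with a non-positive control mean are flagged
    invalid and returned separately.

    Returns (normalized, invalid_rows); normalized columns are row_id,
    cell_line, compound, concentration, viability.
    """
    required = {"row_id", "cell_line", "compound", "concentration",
                "replicate", "signal", "is_control"}
    missing = required - set(measurements.columns)
    if missing:
        raise ValueError(f"plate table missing columns {sorted(missing)}")
    ctrl = measurements[measurements["is_control"]]
    ctrl_mean = ctrl.groupby("row_id")["signal"].mean()
    treated = measurements[~measurements["is_control"]].copy()
    no_ctrl = set(treated["row_id"]) - set(ctrl_mean.index)
    if no_ctrl:
        raise ValueError(f"rows without DMSO controls: {sorted(no_ctrl)[:5]}")
    bad_rows = ctrl_mean[ctrl_mean <= 0].index
    invalid = treated[treated["row_id"].isin(bad_rows)]
    if len(invalid):
        logger.warning("flagged %d plate rows with non-positive control mean",
                       invalid["row_id"].nunique())
    ok = treated[~treated["row_id"].isin(bad_rows)].copy()
    ok["viability"] = ok["signal"] / ok["row_id"].map(ctrl_mean).astype(float)
    norm = (ok.groupby(["row_id", "cell_line", "compound", "concentration"],
                       as_index=False)["viability"].mean())
    return norm, invalid


def qc_filter(normalized: pd.DataFrame,
              max_fraction: float = 1.2) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove plate rows whose normalized viability reaches 120% of DMSO.

    A whole plate row is removed iff any of its normalized values is
    greater than or equal to ``max_fraction``; removals are logged.
    """
    breach = normalized.loc[normalized["viability"] >= max_fraction, "row_id"]
    bad = set(breach)
    if bad:
        logger.info("QC removed plate rows: %s", sorted(bad))
    kept = normalized[~normalized["row_id"].isin(bad)].reset_index(drop=True)
    removed = normalized[normalized["row_id"].isin(bad)].reset_index(drop=True)
    return kept, removed


def compare_validation(
    predicted: pd.DataFrame,
    measured: pd.DataFrame,
    r2_mode: str = "pearson",
) -> tuple[float, float, pd.DataFrame]:
    """Join predictions with measurements on (cell line, compound,
    concentration) and score agreement.

    The prediction value column may be named ``predicted`` or
    ``viability``; the measurement column ``viability`` or ``measured``.
    Requires >= 3 matched pairs; unmatched keys are reported in
    ``paired.attrs['unmatched']``.
    """
    pred = predicted.rename(columns={"viability": "predicted"})
    meas = measured.rename(columns={"viability": "measured"})
    paired = pred[KEY_COLS + ["predicted"]].merge(
        meas[KEY_COLS + ["measured"]], on=KEY_COLS, how="inner")
    if paired.empty:
        raise ValueError("no overlapping (cell line, compound, "
                         "concentration) keys")
    if len(paired) < 3:
        raise ValueError(f"only {len(paired)} matched pairs; need >= 3")
    n_unmatched = len(pred) + len(meas) - 2 * len(paired)
    paired.attrs["unmatched"] = n_unmatched
    if n_unmatched:
        logger.info("%d unmatched records in validation join", n_unmatched)
    r2, rmse = evaluate(paired["predicted"], paired["measured"],
                        r2_mode=r2_mode)
    return r2, rmse, paired
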