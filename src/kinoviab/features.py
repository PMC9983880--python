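"""Design-matrix assembly and correlation-based feature screening.

Each row of the design matrix is one (cell line, compound, concentration)
treatment; inhibition-state columns (act_*) vary with (compound,
concentration), omics columns (exp_/cnv_/prot_/dep_) are broadcast per
cell line, and the response is the imputed relative viability.  Features
are screened by Pearson correlation with the response and selected in
absolute-correlation rank order.
"""

from __future__ import annotations

import logging
from functools import reduce

import numpy as np
import pandas as pd

from .preprocess import CLASS_PREFIXES, InhibitionProfile

logger = logging.getLogger(__name__)

KEY_COLS = ["cell_line", "compound", "concentration"]
RESPONSE_COL = "viability"


def feature_class(name: str) -> str:
    for cls, prefix in CLASS_PREFIXES.items():
        if name.startswith(prefix):
            return cls
    return "other"


def feature_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in KEY_COLS + [RESPONSE_COL]]


def assemble_design(
    viability_records: pd.DataFrame,
    profile: InhibitionProfile,
    omics: dict[str, pd.DataFrame],
    classes: tuple[str, ...] = ("expression",),
) -> pd.DataFrame:
    """Join viability, inhibition states and omics into one flat table.

    Only cell lines present in every requested omics class survive; rows of
    dropped lines are removed with a log entry.  Omics frames must already
    be class-prefixed (see :func:`kinoviab.preprocess.prefix_features`).
    """
    unknown = [c for c in classes if c not in CLASS_PREFIXES or c == "inhibition"]
    if unknown:
        raise ValueError(f"unknown omics classes requested: {unknown}")
    missing = [c for c in classes if c not in omics]
    if missing:
        raise ValueError(f"requested classes absent from bundle: {missing}")

    lines_per_class = [set(omics[c].index) for c in classes]
    shared = reduce(set.intersection, lines_per_class) if lines_per_class \
        else set(viability_records["cell_line"])
    dropped = sorted(set(viability_records["cell_line"]) - shared)
    if dropped:
        logger.info("dropping %d cell lines absent from requested omics: %s",
                    len(dropped), dropped[:10])

    table = viability_records[viability_records["cell_line"].isin(shared)].copy()
    act = profile.to_frame()
    table = table.merge(act, on=["compound", "concentration"], how="inner",
                        validate="many_to_one")
    for cls in classes:
        om = omics[cls]
        table = table.merge(om, left_on="cell_line", right_index=True,
                            how="inner")
    table = table.reset_index(drop=True)
    if table.isna().any().any():
        raise ValueError("assembled design matrix contains missing cells")
    return table


def correlate_features(table: pd.DataFrame) -> pd.DataFrame:
    """Pearson r of every feature column against the viability response.

    Zero-variance features get r = 0 and are flagged so the ranking stays a
    total order.  Requires >= 3 rows and a non-constant response.

    Returns a DataFrame (feature, r, abs_r, class, zero_variance, rank)
    sorted by rank; rank orders by |r| descending with lexicographic
    tie-break on the feature name.
    """
    if len(table) < 3:
        raise ValueError("need at least 3 rows to correlate")
    y = table[RESPONSE_COL].to_numpy(dtype=float)
    y_c = y - y.mean()
    sy = np.sqrt(np.sum(y_c ** 2))
    if sy == 0:
        raise ValueError("zero-variance response")
    feats = feature_columns(table)
    X = table[feats].to_numpy(dtype=float)
    X_c = X - X.mean(axis=0)
    sx = np.sqrt(np.sum(X_c ** 2, axis=0))
    zero_var = sx == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (X_c.T @ y_c) / (sx * sy)
    r[zero_var] = 0.0
    ranking = pd.DataFrame({
        "feature": feats,
        "r": r,
        "abs_r": np.abs(r),
        "class": [feature_class(f) for f in feats],
        "zero_variance": zero_var,
    })
    ranking = ranking.sort_values(["abs_r", "feature"],
                                  ascending=[False, True],
                                  kind="mergesort").reset_index(drop=True)
    ranking["rank"] = np.arange(1, len(ranking) + 1)
    return ranking


def rank_and_select(ranking: pd.DataFrame, k: int,
                    signed: bool = False) -> list[str]:
    """Top-k features by correlation rank.

    Default ranks by |r| descending (strong negative predictors are kept);
    ``signed=True`` ranks by r descending instead.  Ties break
    lexicographically on the feature name; the result for k1 < k2 is always
    a prefix of the result for k2.
    """
    n = len(ranking)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    key = "r" if signed else "abs_r"
    ordered = ranking.sort_values([key, "feature"], ascending=[False, True],
                                  kind="mergesort")
    return ordered["feature"].head(k).tolist()


def selection_order_curves(ranking: pd.DataFrame,
                           max_rank: int | None = None) -> pd.DataFrame:
    """Per-class counts and percentages along the selection rank cutoff.

    For each cutoff 1..max_rank, reports how many features of each class
    are selected (counts across classes sum to the cutoff) and what percent
    of that class that represents.
    """
    ordered = ranking.sort_values("rank")
    classes = ordered["class"].to_numpy()
    max_rank = len(ordered) if max_rank is None else min(max_rank, len(ordered))
    class_sizes = ordered["class"].value_counts()
    rows = []
    counts: dict[str, int] = {c: 0 for c in class_sizes.index}
    for cutoff in range(1, max_rank + 1):
        counts[classes[cutoff - 1]] += 1
        for cls, n_cls in class_sizes.items():
            rows.append((cutoff, cls, counts[cls], 100.0 * counts[cls] / n_cls))
    return pd.DataFrame(rows, columns=["rank", "class", "count", "percent"])


def selection_stability(per_fold_selections) -> tuple[float, pd.Series]:
    """Overlap of per-fold feature selections.

    Returns (|intersection| / |union|, per-feature fraction of folds that
    selected it).  Requires at least two fold selections.
    """
    sets = [set(s) for s in per_fold_selections]
    if len(sets) < 2:
        raise ValueError("need selections from at least 2 folds")
    union = set.union(*sets)
    inter = set.intersection(*sets)
    frac = len(inter) / len(union) if union else 1.0
    inclusion = pd.Series(
        {f: sum(f in s for s in sets) / len(sets) for f in sorted(union)},
        dtype=float)
    return frac, inclusion


def pick_max_variance_dose(viability_records: pd.DataFrame) -> dict[str, float]:
    """Per compound, the grid dose with highest across-cell-line variance.

    Ties go to the lower concentration.  Compounds observed in fewer than
    two cell lines carry no variance and are excluded with a log entry.
    """
    out: dict[str, float] = {}
    for cmpd, grp in viability_records.groupby("compound"):
        if grp["cell_line"].nunique() < 2:
            logger.info("compound %s has <2 cell lines; excluded from "
                        "single-dose selection", cmpd)
            continue
        var = grp.groupby("concentration")["viability"].var(ddof=1).fillna(0.0)
        best = var.max()
        out[cmpd] = float(min(var.index[var == best]))
    return out
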