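"""Relative-viability imputation from four-parameter log-logistic curves.

Secondary viability screens report fitted dose-response parameters rather
than measurements at every concentration of interest.  To place viability
on the same 8-point concentration grid as the kinome inhibition assay, the
fitted LL.4 curve

    f(x) = c + (d - c) / (1 + exp(b * (ln x - ln e)))

(slope b, lower asymptote c, upper asymptote d, inflection concentration e;
the `drc` parameterization, natural log) is evaluated at each grid
concentration.  Parameter sets implying enhanced growth with increasing
dose are filtered out before imputation.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def ll4(x, b, c, d, e):
    """Evaluate the four-parameter log-logistic curve at concentration x.

    Parameters
    ----------
    x : float or array-like
        Concentration(s) in molar; must be strictly positive.
    b, c, d, e : float
        Slope, lower asymptote, upper asymptote, inflection concentration
        (e > 0).

    Returns
    -------
    float or ndarray
        c + (d - c) / (1 + exp(b * (ln x - ln e))).
    """
    x_arr = np.asarray(x, dtype=float)
    if np.any(x_arr <= 0):
        raise ValueError("concentration must be > 0")
    if e <= 0:
        raise ValueError("inflection concentration e must be > 0")
    out = c + (d - c) / (1.0 + np.exp(b * (np.log(x_arr) - np.log(e))))
    return float(out) if np.isscalar(x) else out


def impute_viability(
    params: pd.DataFrame,
    dose_grid,
    clip_max: float | None = None,
) -> pd.DataFrame:
    """One viability record per (cell line, compound, grid concentration).

    Combos with non-finite parameters are skipped with a log entry.  When
    ``clip_max`` is given, values are clipped to [0, clip_max]; by default
    no clipping is applied (fitted curves legitimately exceed 1).

    Returns a long DataFrame (cell_line, compound, concentration, viability).
    """
    grid = np.asarray(dose_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("dose_grid must be nonempty")
    frames = []
    n_skipped = 0
    vals = params[["b", "c", "d", "e"]].to_numpy(dtype=float)
    finite = np.isfinite(vals).all(axis=1) & (vals[:, 3] > 0)
    for keep, (_, row) in zip(finite, params.iterrows()):
        if not keep:
            n_skipped += 1
            logger.warning("non-finite LL.4 parameters for (%s, %s); skipped",
                           row["cell_line"], row["compound"])
            continue
        v = ll4(grid, row["b"], row["c"], row["d"], row["e"])
        if clip_max is not None:
            v = np.clip(v, 0.0, clip_max)
        frames.append(pd.DataFrame({
            "cell_line": row["cell_line"],
            "compound": row["compound"],
            "concentration": grid,
            "viability": v,
        }))
    if n_skipped:
        logger.info("skipped %d combos with invalid parameters", n_skipped)
    if not frames:
        return pd.DataFrame(columns=["cell_line", "compound",
                                     "concentration", "viability"])
    out = pd.concat(frames, ignore_index=True)
    out.attrs["clip_max"] = clip_max
    return out


def filter_growth_enhancing(
    params: pd.DataFrame,
    dose_grid,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a parameter table into (kept, removed) by the growth check.

    A combo is removed iff its curve value at the highest grid dose exceeds
    the value at the lowest dose, i.e. the fitted curve implies enhanced
    growth with increasing compound concentration.  For monotone LL.4
    curves this endpoint comparison is equivalent to a full monotonicity
    check over the grid.
    """
    grid = np.asarray(dose_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("dose_grid must be nonempty")
    lo, hi = float(grid.min()), float(grid.max())
    increasing = np.array([
        ll4(hi, r.b, r.c, r.d, r.e) > ll4(lo, r.b, r.c, r.d, r.e)
        for r in params.itertuples()
    ], dtype=bool) if len(params) else np.zeros(0, dtype=bool)
    kept = params.loc[~increasing].reset_index(drop=True)
    removed = params.loc[increasing].reset_index(drop=True)
    if len(removed):
        logger.info("growth filter removed %d of %d combos",
                    len(removed), len(params))
    return kept, removed
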