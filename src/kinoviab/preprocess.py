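"""Cleaning rules for kinome inhibition profiles and baseline omics.

Inhibition records arrive sparse: only proteins affected by a compound are
listed.  Densification fills absent (compound, protein) pairs with the
neutral relative intensity 1.0, isolated single-concentration gaps are
filled as the mean of the two nearest concentrations, and rare outlier
intensities are truncated to a global high percentile (99.99 by default).

Omics matrices get class prefixes so that features derived from the same
gene in different assays stay distinct, proteomics missing values are
imputed to (per-protein minimum - one SD), and rows with residual missing
entries are dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CLASS_PREFIXES = {
    "inhibition": "act_",
    "expression": "exp_",
    "cnv": "cnv_",
    "proteomics": "prot_",
    "dependency": "dep_",
}


@dataclass
class InhibitionProfile:
    """Dense compound x concentration x protein relative-intensity tensor."""

    compounds: list[str]
    proteins: list[str]
    dose_grid: np.ndarray
    intensity: np.ndarray  # shape (n_compounds, n_doses, n_proteins)

    def copy(self) -> "InhibitionProfile":
        return replace(self, intensity=self.intensity.copy(),
                       dose_grid=np.asarray(self.dose_grid, dtype=float).copy())

    def to_frame(self) -> pd.DataFrame:
        """Wide layout: one row per (compound, concentration), act_* columns."""
        n_c, n_x, _ = self.intensity.shape
        idx = pd.MultiIndex.from_product(
            [self.compounds, self.dose_grid],
            names=["compound", "concentration"])
        flat = self.intensity.reshape(n_c * n_x, -1)
        cols = [CLASS_PREFIXES["inhibition"] + p for p in self.proteins]
        return pd.DataFrame(flat, index=idx, columns=cols).reset_index()


def densify_inhibition(
    records: pd.DataFrame,
    compounds,
    proteins,
    dose_grid,
) -> InhibitionProfile:
    """Fill the default intensity of 1.0 for every unlisted pair.

    Pairs with at least one record keep their recorded values verbatim;
    their unrecorded concentrations are left as NaN for the gap-imputation
    step.  Pairs with no records at all are fully neutral (1.0).

    Raises ValueError naming the offending record if a concentration is not
    a member of the grid (exact match after float canonicalization).
    """
    compounds = list(compounds)
    proteins = list(proteins)
    grid = np.asarray(dose_grid, dtype=float)
    c_idx = {c: i for i, c in enumerate(compounds)}
    p_idx = {p: i for i, p in enumerate(proteins)}
    x_idx = {float(x): i for i, x in enumerate(grid)}

    tensor = np.ones((len(compounds), grid.size, len(proteins)))
    pairs = set()
    triples: list[tuple[int, int, int, float]] = []
    for rec in records.itertuples(index=False):
        conc = float(rec.concentration)
        if conc not in x_idx:
            raise ValueError(
                f"record ({rec.compound}, {rec.protein}, {rec.concentration}) "
                "has a concentration not on the dose grid")
        if rec.compound not in c_idx:
            raise ValueError(f"unknown compound {rec.compound!r} in records")
        if rec.protein not in p_idx:
            raise ValueError(f"unknown protein {rec.protein!r} in records")
        ci, pi = c_idx[rec.compound], p_idx[rec.protein]
        pairs.add((ci, pi))
        triples.append((ci, x_idx[conc], pi, float(rec.relative_intensity)))
    for ci, pi in pairs:
        tensor[ci, :, pi] = np.nan
    for ci, xi, pi, v in triples:
        tensor[ci, xi, pi] = v
    return InhibitionProfile(compounds, proteins, grid, tensor)


def impute_missing_concentrations(profile: InhibitionProfile) -> InhibitionProfile:
    """Fill isolated missing cells as the mean of the two flanking doses.

    Boundary gaps take the nearest available neighbor's value.  Two
    adjacent missing cells in one (compound, protein) series violate the
    isolated-gap premise and raise ValueError.
    """
    out = profile.copy()
    t = out.intensity
    n_filled = 0
    for ci in range(t.shape[0]):
        for pi in range(t.shape[2]):
            series = t[ci, :, pi]
            gaps = np.nonzero(np.isnan(series))[0]
            if gaps.size == 0:
                continue
            if np.any(np.diff(gaps) == 1):
                raise ValueError(
                    f"adjacent missing concentrations for compound "
                    f"{out.compounds[ci]!r}, protein {out.proteins[pi]!r}")
            for i in gaps:
                if i == 0:
                    series[i] = series[1]
                elif i == series.size - 1:
                    series[i] = series[i - 1]
                else:
                    series[i] = 0.5 * (series[i - 1] + series[i + 1])
                n_filled += 1
    if n_filled:
        logger.info("imputed %d missing single-concentration values", n_filled)
    if np.isnan(t).any():
        raise AssertionError("missing cells remain after imputation")
    return out


def truncate_outliers(
    profile: InhibitionProfile,
    percentile: float = 99.99,
) -> tuple[InhibitionProfile, float]:
    """Truncate intensities above a global percentile of the dense tensor.

    The threshold is the linear-interpolation quantile pooled over all
    compounds, doses and proteins; every value above it is set to it.
    Returns (truncated profile, threshold).
    """
    if not 0.0 < percentile <= 100.0:
        raise ValueError(f"percentile must be in (0, 100], got {percentile}")
    out = profile.copy()
    threshold = float(np.percentile(out.intensity, percentile))
    n_over = int(np.sum(out.intensity > threshold))
    out.intensity = np.minimum(out.intensity, threshold)
    logger.info("truncation threshold %.4g (%.2f percentile); %d values truncated",
                threshold, percentile, n_over)
    return out, threshold


def prefix_features(bundle: dict[str, pd.DataFrame]) -> dict[str, pd.DataFrame]:
    """Prefix every omics column with its class tag (exp_/cnv_/prot_/dep_).

    Keeps features derived from the same gene in different assays distinct.
    Raises ValueError on duplicate columns within one class or on an
    unknown class key.
    """
    out = {}
    for cls, df in bundle.items():
        if cls not in CLASS_PREFIXES:
            raise ValueError(f"unknown omics class {cls!r}")
        if df.columns.duplicated().any():
            dupes = df.columns[df.columns.duplicated()].tolist()
            raise ValueError(f"duplicate columns within class {cls!r}: {dupes}")
        renamed = df.copy()
        renamed.columns = [CLASS_PREFIXES[cls] + str(c) for c in df.columns]
        out[cls] = renamed
    return out


def impute_proteomics(matrix: pd.DataFrame) -> pd.DataFrame:
    """Fill missing protein readings with (observed minimum - one SD).

    The fill value is computed per protein column from its observed values
    (sample SD).  Columns with fewer than two observed values cannot define
    an SD and are dropped with a log entry.  An all-missing matrix raises.
    """
    if matrix.isna().all().all():
        raise ValueError("proteomics matrix is entirely missing")
    counts = matrix.notna().sum(axis=0)
    droppable = counts[counts < 2].index.tolist()
    if droppable:
        logger.info("dropping %d proteomics columns with <2 observations: %s",
                    len(droppable), droppable[:10])
    out = matrix.drop(columns=droppable)
    fill = out.min(axis=0) - out.std(axis=0, ddof=1)
    return out.fillna(fill)


def drop_incomplete_lines(matrix: pd.DataFrame) -> pd.DataFrame:
    """Remove cell-line rows carrying any missing entry (logged)."""
    complete = matrix.dropna(axis=0)
    removed = matrix.index.difference(complete.index).tolist()
    if removed:
        logger.info("dropped %d incomplete cell lines: %s",
                    len(removed), removed[:10])
    return complete
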