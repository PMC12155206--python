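"""Participant- and feature-level QC filters, transforms, and standardization.

Boundary semantics are deliberate and strict:

* motion filter keeps mean FD strictly *below* the threshold (default 0.7 mm);
* surface-hole filter excludes counts strictly *above* the maximum (default 380);
* tract filter drops tracts whose unusable-data fraction is strictly *above*
  the maximum (default 3%), so a tract at exactly 3% is retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from neuropls.datatypes import CognitionMatrix, FeatureMatrix, SchemaError

log = logging.getLogger(__name__)

FD_THRESHOLD_MM = 0.7
FD_THRESHOLD_STRICT_MM = 0.5
MAX_SURFACE_HOLES = 380
MAX_UNUSABLE_FRACTION = 0.03


def filter_by_motion(cohort: pd.DataFrame, threshold: float = FD_THRESHOLD_MM) -> pd.DataFrame:
    """Keep participants with mean framewise displacement strictly below
    ``threshold`` (mm). Rows with missing mean FD are rejected with a warning,
    never silently kept. Row order is preserved."""
    if "mean_fd" not in cohort.columns:
        raise SchemaError("cohort table has no mean_fd column")
    missing = cohort["mean_fd"].isna()
    if missing.any():
        log.warning(
            "filter_by_motion: rejecting %d rows with missing mean_fd: %s",
            int(missing.sum()),
            list(cohort.loc[missing, "participant_id"])[:10],
        )
    keep = cohort["mean_fd"] < threshold
    excluded = cohort.loc[~keep & ~missing, "participant_id"]
    if len(excluded):
        log.info("filter_by_motion: excluded %d participants (FD >= %g): %s",
                 len(excluded), threshold, list(excluded)[:10])
    return cohort.loc[keep & ~missing].copy()


def filter_by_surface_holes(cohort: pd.DataFrame, max_holes: int = MAX_SURFACE_HOLES) -> pd.DataFrame:
    """Exclude participants whose surface-hole count exceeds ``max_holes``
    (strict ``>``: a count of exactly ``max_holes`` is kept)."""
    if "surface_holes" not in cohort.columns:
        raise SchemaError("cohort table has no surface_holes column")
    holes = cohort["surface_holes"]
    if (holes.dropna() < 0).any():
        raise SchemaError("surface_holes must be non-negative")
    keep = holes <= max_holes
    excluded = cohort.loc[~keep, "participant_id"]
    if len(excluded):
        log.info("filter_by_surface_holes: excluded %d participants (> %d holes)",
                 len(excluded), max_holes)
    return cohort.loc[keep].copy()


def filter_tracts(features: FeatureMatrix, max_unusable: float = MAX_UNUSABLE_FRACTION) -> FeatureMatrix:
    """Drop white-matter tracts with more than ``max_unusable`` unusable data
    and mean-impute remaining missing cells per tract.

    A tract at exactly the threshold is retained (exclusion is strict ``>``).
    """
    if features.modality != "WM":
        raise SchemaError("filter_tracts applies to WM (tract FA) matrices only")
    if features.unusable is None:
        raise SchemaError("WM feature matrix has no per-tract unusable fractions")
    unusable = features.unusable.reindex(features.data.columns).fillna(0.0)
    keep = unusable <= max_unusable
    dropped = list(unusable.index[~keep])
    if dropped:
        log.info("filter_tracts: dropped %d tracts with >%g%% unusable data: %s",
                 len(dropped), 100 * max_unusable, dropped[:10])
    if not keep.any():
        raise ValueError("all tracts exceed the unusable-data threshold")
    data = features.data.loc[:, keep].copy()
    for col in data.columns[data.isna().any()]:
        data[col] = data[col].fillna(data[col].mean())
    return FeatureMatrix(data, "WM", unusable[keep])


def impute_cognition_mean(cog: CognitionMatrix) -> CognitionMatrix:
    """Replace missing cognitive scores with the observed per-test mean.

    Observed cells are unchanged; the missingness mask is retained for audit.
    A fully missing test is an error (there is no mean to impute).
    """
    data = cog.data.copy()
    fully_missing = [c for c in data.columns if data[c].isna().all()]
    if fully_missing:
        raise ValueError(f"cannot mean-impute fully missing tests: {fully_missing}")
    mask = data.isna()
    data = data.fillna(data.mean())
    n_imputed = int(mask.to_numpy().sum())
    if n_imputed:
        log.info("impute_cognition_mean: imputed %d of %d cells (%.1f%%)",
                 n_imputed, mask.size, 100 * n_imputed / mask.size)
    return CognitionMatrix(data, dict(cog.domains), missing_mask=mask)


def transform_wmh(wmh_volume, icv):
    """ICV-correct and square-root transform white-matter-hyperintensity
    volume: ``sqrt(wmh / icv)``. The square root normalizes the heavily
    right-skewed lesion-volume distribution."""
    wmh = np.asarray(wmh_volume, dtype=float)
    icv_a = np.asarray(icv, dtype=float)
    if (icv_a <= 0).any():
        raise ValueError("icv must be positive")
    if (wmh < 0).any():
        raise ValueError("wmh_volume must be non-negative")
    return np.sqrt(wmh / icv_a)


@dataclass
class ColumnScaler:
    """Per-column standardization parameters fitted on a training sample, so
    held-out data can be standardized without leakage."""

    mean: pd.Series
    sd: pd.Series

    def transform(self, frame: pd.DataFrame) -> pd.DataFrame:
        missing = [c for c in self.mean.index if c not in frame.columns]
        if missing:
            raise SchemaError(f"columns missing at transform time: {missing}")
        cols = list(self.mean.index)
        return (frame[cols] - self.mean) / self.sd

    def inverse_transform(self, frame: pd.DataFrame) -> pd.DataFrame:
        return frame[list(self.mean.index)] * self.sd + self.mean


def zscore_columns(matrix: pd.DataFrame) -> tuple[pd.DataFrame, ColumnScaler]:
    """Z-score every column (sample sd, n-1 denominator).

    Returns the standardized matrix and the fitted :class:`ColumnScaler` so
    held-out data can be standardized with training parameters. Zero-variance
    columns are an error naming the column, never silently zeroed.
    """
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 rows to standardize")
    if matrix.isna().any().any():
        bad = list(matrix.columns[matrix.isna().any()])
        raise ValueError(f"cannot standardize columns with missing values: {bad[:5]}")
    mean = matrix.mean()
    sd = matrix.std(ddof=1)
    zero_var = list(sd.index[(sd == 0) | sd.isna()])
    if zero_var:
        raise ValueError(f"zero-variance columns cannot be standardized: {zero_var[:5]}")
    scaler = ColumnScaler(mean=mean, sd=sd)
    return (matrix - mean) / sd, scaler
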