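"""Tabular containers for cohort, cognition, and brain-feature data.

All containers are thin wrappers around :class:`pandas.DataFrame`, indexed by
``participant_id``, so that row alignment between the clinical table, the
cognitive battery, and each imaging-feature matrix is explicit and checkable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MODALITIES = ("FC", "WM", "GM")

#: Columns expected in a participant (cohort) table, with short descriptions.
COHORT_COLUMNS = {
    "participant_id": "unique participant identifier",
    "site": "acquisition site label",
    "age": "age in years",
    "sex": "binary sex indicator (1 = female)",
    "education": "education in years",
    "madrs_baseline": "baseline MADRS depression severity (0-60)",
    "madrs_change": "MADRS change from baseline to treatment endpoint",
    "remission": "binary remission label (endpoint MADRS <= 10)",
    "athf": "ATHF treatment-resistance score",
    "cirs_g": "CIRS-G medical-burden score",
    "mean_fd": "mean framewise displacement (mm)",
    "icv": "intracranial volume (mm^3)",
    "wmh_volume": "white-matter hyperintensity volume (mm^3)",
    "centile": "brain-structure centile (0-1)",
    "surface_holes": "FreeSurfer surface-hole count",
}

#: The 12-test cognitive battery grouped into 6 domains (2 tests per domain).
DEFAULT_COGNITIVE_DOMAINS = {
    "digit_span": "attention",
    "trails_a": "attention",
    "list_learning": "immediate_memory",
    "story_memory": "immediate_memory",
    "list_recall": "delayed_memory",
    "figure_recall": "delayed_memory",
    "naming": "language",
    "semantic_fluency": "language",
    "figure_copy": "visuospatial",
    "line_orientation": "visuospatial",
    "trails_b": "executive",
    "letter_fluency": "executive",
}


class SchemaError(ValueError):
    """Raised when a table does not match its expected schema."""


def validate_cohort(cohort: pd.DataFrame, required: tuple[str, ...] | None = None) -> None:
    """Check a cohort table against the expected schema.

    Parameters
    ----------
    cohort
        Participant table, one row per participant.
    required
        Column names that must be present. Defaults to all of
        :data:`COHORT_COLUMNS`.

    Raises
    ------
    SchemaError
        On missing columns, duplicate participant IDs, negative motion, or
        non-positive intracranial volume.
    """
    required = required if required is not None else tuple(COHORT_COLUMNS)
    missing = [c for c in required if c not in cohort.columns]
    if missing:
        raise SchemaError(f"cohort table is missing columns: {missing}")
    if cohort["participant_id"].duplicated().any():
        dupes = cohort.loc[cohort["participant_id"].duplicated(), "participant_id"]
        raise SchemaError(f"duplicate participant_id values: {sorted(set(dupes))[:5]}")
    if "mean_fd" in cohort.columns and (cohort["mean_fd"].dropna() < 0).any():
        raise SchemaError("mean_fd must be non-negative")
    if "icv" in cohort.columns and (cohort["icv"].dropna() <= 0).any():
        raise SchemaError("icv must be positive")


@dataclass
class FeatureMatrix:
    """Participants x brain features for one imaging modality.

    Attributes
    ----------
    data
        Feature values, indexed by ``participant_id``.
    modality
        One of ``"FC"`` (functional-connectivity edges), ``"WM"``
        (white-matter tract FA), ``"GM"`` (gray-matter structure).
    unusable
        Per-feature fraction of unusable data (WM tractography only).
    """

    data: pd.DataFrame
    modality: str
    unusable: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise SchemaError(
                f"modality must be one of {MODALITIES}, got {self.modality!r}"
            )
        if self.unusable is not None:
            extra = set(self.unusable.index) - set(self.data.columns)
            if extra:
                raise SchemaError(f"unusable fractions for unknown features: {sorted(extra)[:5]}")

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def subset_participants(self, ids) -> "FeatureMatrix":
        return FeatureMatrix(self.data.loc[ids], self.modality, self.unusable)


def fc_edge_names(n_components: int, prefix: str = "IC") -> list[str]:
    """Names for the upper-triangle edges among ``n_components`` networks.

    k components give k*(k-1)/2 pairwise connectivities (k=21 -> 210).
    """
    names = []
    for i in range(1, n_components + 1):
        for j in range(i + 1, n_components + 1):
            names.append(f"{prefix}{i:02d}-{prefix}{j:02d}")
    return names


@dataclass
class CognitionMatrix:
    """Participants x cognitive test scores, with domain labels and a
    missingness mask retained for audit after imputation."""

    data: pd.DataFrame
    domains: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_COGNITIVE_DOMAINS))
    missing_mask: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        unknown = [c for c in self.data.columns if c not in self.domains]
        if unknown:
            raise SchemaError(f"cognitive tests without a domain label: {unknown}")
        if self.missing_mask is None:
            self.missing_mask = self.data.isna()

    @property
    def test_names(self) -> list[str]:
        return list(self.data.columns)

    def subset_participants(self, ids) -> "CognitionMatrix":
        return CognitionMatrix(
            self.data.loc[ids], dict(self.domains), self.missing_mask.loc[ids]
        )


def check_aligned(*frames: pd.DataFrame) -> None:
    """Raise if the row indices of the given frames are not identical."""
    first = frames[0].index
    for f in frames[1:]:
        if len(f.index) != len(first) or not (f.index == first).all():
            raise SchemaError("tables are not row-aligned on participant_id")
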