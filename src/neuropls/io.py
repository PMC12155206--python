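"""Delimited-text readers and writers for all pipeline tables.

Every artifact is plain comma-separated text with a header row and
``participant_id`` as the first column, so intermediate results remain
auditable with standard tools. The synthetic ground truth is serialized to
a YAML sidecar.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from neuropls.datatypes import (
    CognitionMatrix,
    FeatureMatrix,
    validate_cohort,
)
from neuropls.synthetic import SyntheticTruth


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)


def read_cohort(path, validate: bool = True) -> pd.DataFrame:
    cohort = pd.read_csv(path)
    if validate:
        validate_cohort(cohort)
    return cohort


def write_cognition(cog: CognitionMatrix, path) -> None:
    """Scores table plus a ``*_domains.csv`` sidecar with test->domain labels
    and a ``*_mask.csv`` sidecar with the missingness mask."""
    path = Path(path)
    cog.data.rename_axis("participant_id").to_csv(path)
    pd.Series(cog.domains, name="domain").rename_axis("test").to_csv(
        path.with_name(path.stem + "_domains.csv"))
    cog.missing_mask.rename_axis("participant_id").astype(int).to_csv(
        path.with_name(path.stem + "_mask.csv"))


def read_cognition(path) -> CognitionMatrix:
    path = Path(path)
    data = pd.read_csv(path, index_col="participant_id")
    domains = pd.read_csv(path.with_name(path.stem + "_domains.csv"),
                          index_col="test")["domain"].to_dict()
    mask_path = path.with_name(path.stem + "_mask.csv")
    mask = None
    if mask_path.exists():
        mask = pd.read_csv(mask_path, index_col="participant_id").astype(bool)
    return CognitionMatrix(data, domains, mask)


def write_features(fm: FeatureMatrix, path) -> None:
    path = Path(path)
    fm.data.rename_axis("participant_id").to_csv(path)
    if fm.unusable is not None:
        fm.unusable.rename("unusable").rename_axis("feature").to_csv(
            path.with_name(path.stem + "_unusable.csv"))


def read_features(path, modality: str) -> FeatureMatrix:
    path = Path(path)
    data = pd.read_csv(path, index_col="participant_id")
    unus_path = path.with_name(path.stem + "_unusable.csv")
    unusable = None
    if unus_path.exists():
        unusable = pd.read_csv(unus_path, index_col="feature")["unusable"]
    return FeatureMatrix(data, modality, unusable)


def write_truth(truth: SyntheticTruth, path) -> None:
    doc = {
        "informative_feature_ids": list(truth.informative_feature_ids),
        "outcome_coefficients": truth.outcome_coefficients.tolist(),
        "outcome_slope": float(truth.outcome_slope),
        "outcome_intercept": float(truth.outcome_intercept),
        "covariate_slopes": {k: float(v) for k, v in truth.covariate_slopes.items()},
        "planted_variance_explained": float(truth.planted_variance_explained),
        "seed": int(truth.seed),
        "factor_loadings_Y": truth.factor_loadings_Y.tolist(),
        "factor_loadings_X": {m: L.tolist() for m, L in truth.factor_loadings_X.items()},
        "site_location": {m: g.tolist() for m, g in truth.site_location.items()},
        "site_scale": {m: d.tolist() for m, d in truth.site_scale.items()},
        "factor_scores": truth.factor_scores.tolist(),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh)


def read_truth(path) -> SyntheticTruth:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return SyntheticTruth(
        factor_scores=np.asarray(doc["factor_scores"], dtype=float),
        factor_loadings_X={m: np.asarray(L, dtype=float)
                           for m, L in doc["factor_loadings_X"].items()},
        factor_loadings_Y=np.asarray(doc["factor_loadings_Y"], dtype=float),
        informative_feature_ids=doc["informative_feature_ids"],
        outcome_coefficients=np.asarray(doc["outcome_coefficients"], dtype=float),
        outcome_slope=doc["outcome_slope"],
        outcome_intercept=doc["outcome_intercept"],
        site_location={m: np.asarray(g, dtype=float)
                       for m, g in doc["site_location"].items()},
        site_scale={m: np.asarray(d, dtype=float)
                    for m, d in doc["site_scale"].items()},
        covariate_slopes=doc["covariate_slopes"],
        planted_variance_explained=doc["planted_variance_explained"],
        seed=doc["seed"],
    )


def write_dataset(outdir, cohort, cognition, features, truth=None) -> None:
    """Write a full synthetic or ingested dataset to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_cohort(cohort, outdir / "cohort.csv")
    write_cognition(cognition, outdir / "cognition.csv")
    for modality, fm in features.items():
        write_features(fm, outdir / f"features_{modality}.csv")
    if truth is not None:
        write_truth(truth, outdir / "truth.yaml")


def read_dataset(indir, modalities=("FC", "WM", "GM")):
    indir = Path(indir)
    cohort = read_cohort(indir / "cohort.csv")
    cognition = read_cognition(indir / "cognition.csv")
    features = {}
    for m in modalities:
        p = indir / f"features_{m}.csv"
        if p.exists():
            features[m] = read_features(p, m)
    truth = None
    if (indir / "truth.yaml").exists():
        truth = read_truth(indir / "truth.yaml")
    return cohort, cognition, features, truth
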