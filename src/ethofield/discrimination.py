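"""LDA genotype discrimination from behavioral feature sets.

Five per-animal feature sets are compared as inputs to a plain linear
discriminant analysis separating WT, HE and KO:

=========  =======================================================  ====
set        columns                                                  n
=========  =======================================================  ====
movements  time fraction + bout frequency of each of 13 movements   26
grooming   grooming fraction + frequency                             2
distance   total distance travelled (mm)                             1
position   time fraction in the traditional center and perimeter     2
clusters   fraction + frequency of each of 5 clusters               10
=========  =======================================================  ====

Sexes are modeled separately.  Features are z-scored per column; the LDA
uses the eigen solver with automatic (Ledoit-Wolf) within-class covariance
shrinkage, which keeps the 26-feature / ~15-animals-per-class regime well
posed.  Performance is summarized by the row-normalized 3x3 confusion
matrix under leave-one-out cross-validation and its diagonal mean — the
*discrimination* score (mean per-class recall, 1 = perfect, chance 1/3).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import LeaveOneOut, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .metrics import time_budget, total_distance
from .ontology import (
    CLUSTERS,
    DEFAULT_CLUSTER_MAP,
    GENOTYPES,
    MOVEMENTS,
    Cohort,
)
from .zoning import ZoneDivision, traditional_division, zone_metrics

__all__ = [
    "FEATURE_SETS",
    "FeatureTable",
    "DiscriminationResult",
    "build_features",
    "fit_lda",
    "evaluate",
]

logger = logging.getLogger(__name__)

FEATURE_SETS = ("movements", "grooming", "distance", "position", "clusters")


@dataclass
class FeatureTable:
    """Per-animal feature matrix with genotype/sex labels."""

    X: pd.DataFrame  # rows: animals; columns: features
    genotype: pd.Series
    sex: pd.Series
    feature_set: str

    def __post_init__(self) -> None:
        if self.X.isna().any().any():
            raise ValueError("feature table contains missing values")


@dataclass
class DiscriminationResult:
    """Projection, row-normalized confusion matrix and discrimination score."""

    projection: pd.DataFrame  # per-animal discriminant coordinates (<= 2 axes)
    confusion: pd.DataFrame  # true x predicted, rows sum to 1
    discrimination: float  # mean of the confusion diagonal
    accuracy: float  # overall fraction correct


def build_features(
    cohort: Cohort,
    feature_set: str,
    division: ZoneDivision | None = None,
    sex: str | None = None,
) -> FeatureTable:
    """Assemble one feature set for (optionally one sex of) a cohort."""
    if feature_set not in FEATURE_SETS:
        raise ValueError(f"unknown feature_set {feature_set!r}; one of {FEATURE_SETS}")
    if division is None:
        division = traditional_division()
    subjects = cohort.select(sex=sex)
    if not subjects:
        raise ValueError("no animals selected")

    rows: list[dict[str, float]] = []
    for s in subjects:
        eth = cohort.ethograms[s.animal_id]
        traj = cohort.trajectories[s.animal_id]
        feats: dict[str, float] = {}
        if feature_set == "movements":
            tb = time_budget(eth)
            for m in MOVEMENTS:
                feats[f"frac_{m}"] = tb.fractions[m]
                feats[f"freq_{m}"] = tb.frequencies[m]
        elif feature_set == "grooming":
            tb = time_budget(eth)
            feats["frac_grooming"] = tb.fractions["grooming"]
            feats["freq_grooming"] = tb.frequencies["grooming"]
        elif feature_set == "distance":
            feats["total_distance_mm"] = total_distance(traj)
        elif feature_set == "position":
            zm = zone_metrics(eth, traj, division)
            feats["frac_center"] = zm.fractions["center"]
            feats["frac_perimeter"] = zm.fractions["perimeter"]
        elif feature_set == "clusters":
            tb = time_budget(eth, DEFAULT_CLUSTER_MAP)
            for c in CLUSTERS:
                feats[f"frac_{c}"] = tb.fractions[c]
                feats[f"freq_{c}"] = tb.frequencies[c]
        rows.append(feats)

    index = [s.animal_id for s in subjects]
    return FeatureTable(
        X=pd.DataFrame(rows, index=index),
        genotype=pd.Series([s.genotype for s in subjects], index=index),
        sex=pd.Series([s.sex for s in subjects], index=index),
        feature_set=feature_set,
    )


def _lda_pipeline(shrinkage="auto") -> Pipeline:
    # eigen solver + Ledoit-Wolf shrinkage: robust to singular within-class
    # covariance (few animals, many or duplicated features)
    return Pipeline(
        [
            ("scale", StandardScaler()),
            ("lda", LinearDiscriminantAnalysis(solver="eigen", shrinkage=shrinkage)),
        ]
    )


def _fit_pipe(X: np.ndarray, y: np.ndarray) -> Pipeline:
    """Fit scaler+LDA; fall back to fixed shrinkage if the automatically
    shrunk within-class scatter is still not positive definite (degenerate
    single-sample classes)."""
    pipe = _lda_pipeline()
    try:
        pipe.fit(X, y)
        return pipe
    except np.linalg.LinAlgError:
        logger.warning(
            "auto-shrunk within-class covariance not positive definite; "
            "refitting with fixed shrinkage 0.5"
        )
        pipe = _lda_pipeline(shrinkage=0.5)
        pipe.fit(X, y)
        return pipe


def fit_lda(features: FeatureTable) -> tuple[pd.DataFrame, Pipeline]:
    """Fit LDA on the whole table; return per-animal discriminant coordinates.

    With 3 classes the projection has at most 2 axes (deterministic up to
    axis sign).
    """
    classes = features.genotype.unique()
    if len(classes) < 2:
        raise ValueError("need >= 2 genotype classes to fit LDA")
    counts = features.genotype.value_counts()
    if (counts < 3).any():
        logger.warning("fewer than 3 animals in class(es): %s",
                       counts[counts < 3].index.tolist())
    pipe = _fit_pipe(features.X.to_numpy(), features.genotype.to_numpy())
    Z = pipe.transform(features.X.to_numpy())
    n_axes = min(2, Z.shape[1])
    proj = pd.DataFrame(
        Z[:, :n_axes],
        index=features.X.index,
        columns=[f"LD{i + 1}" for i in range(n_axes)],
    )
    return proj, pipe


def evaluate(
    features: FeatureTable,
    cv: str = "loo",
    seed: int = 0,
    n_splits: int = 5,
) -> DiscriminationResult:
    """Cross-validated genotype prediction.

    ``cv='loo'`` (default): each animal is predicted by an LDA fit on all
    others.  ``cv='stratified'``: shuffled stratified k-fold seeded by
    *seed*.  Confusion rows are normalized by true-class counts;
    discrimination is the diagonal mean.
    """
    X = features.X.to_numpy()
    y = features.genotype.to_numpy()
    present = [g for g in GENOTYPES if g in set(y)]
    if len(present) < 2:
        raise ValueError("need >= 2 genotype classes")

    if cv == "loo":
        splitter = LeaveOneOut()
    elif cv == "stratified":
        splitter = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    else:
        raise ValueError("cv must be 'loo' or 'stratified'")

    y_pred = np.empty_like(y)
    for k, (tr, te) in enumerate(splitter.split(X, y)):
        if set(y[tr]) != set(present):
            raise ValueError(f"fold {k}: a class is absent from training")
        pipe = _fit_pipe(X[tr], y[tr])
        y_pred[te] = pipe.predict(X[te])

    confusion = pd.DataFrame(0.0, index=present, columns=present)
    for t, p in zip(y, y_pred):
        confusion.loc[t, p] += 1.0
    row = confusion.sum(axis=1)
    confusion = confusion.div(row, axis=0)
    discrimination = float(np.diag(confusion.to_numpy()).mean())
    accuracy = float((y == y_pred).mean())
    projection, _ = fit_lda(features)
    return DiscriminationResult(
        projection=projection,
        confusion=confusion,
        discrimination=discrimination,
        accuracy=accuracy,
    )
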