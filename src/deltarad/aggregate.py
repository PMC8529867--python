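"""Per-patient feature aggregation and delta-radiomics percentage changes.

Outcomes are per patient, so lesion-level features are reduced to one value
per patient and feature: the unweighted mean over that patient's target
lesions.  Delta features are percentage changes computed per lesion between
baseline and the first post-therapy scan (lesions matched by id), then
averaged across the patient's matched lesions.

Two sign conventions exist for the percentage change::

    as-printed          100 * (var_pre - var_post) / var_pre
    increase-positive   100 * (var_post - var_pre) / var_pre

``as-printed`` follows the published formula (a post-therapy increase gives
a negative value); ``increase-positive`` is its exact negation.  The default
is ``as-printed``; see docs/methods.md for why both are exposed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .texture import FeatureVector

AS_PRINTED = "as-printed"
INCREASE_POSITIVE = "increase-positive"
CONVENTIONS = (AS_PRINTED, INCREASE_POSITIVE)


class AggregationError(ValueError):
    pass


@dataclass
class PatientFeatures:
    """Per-patient mean of each (statistic, scale) over target lesions.

    ``n_per_feature`` records how many lesions contributed to each entry;
    entries undefined in every lesion remain NaN with n = 0.
    """

    patient_id: str
    timepoint: str
    values: pd.Series
    n_per_feature: pd.Series
    n_lesions: int


@dataclass
class DeltaFeatures:
    """Per-patient mean percentage change over lesions matched across timepoints."""

    patient_id: str
    values: pd.Series
    n_matched: int
    unmatched_lesions: tuple[str, ...] = field(default_factory=tuple)
    sign_convention: str = AS_PRINTED


def _features_frame(features: Sequence[FeatureVector]) -> pd.DataFrame:
    return pd.DataFrame(
        [fv.values for fv in features], index=[fv.lesion_id for fv in features]
    )


def average_over_lesions(features: Sequence[FeatureVector]) -> PatientFeatures:
    """Unweighted arithmetic mean of each feature over a patient's lesions.

    Undefined (NaN) entries are excluded from the mean; the per-feature
    contribution count is kept so downstream code can see partial averages.
    """
    if not features:
        raise AggregationError("no lesion features to average")
    patients = {fv.patient_id for fv in features}
    timepoints = {fv.timepoint for fv in features}
    if len(patients) > 1 or len(timepoints) > 1:
        raise AggregationError(
            f"cannot average across patients {sorted(patients)} / "
            f"timepoints {sorted(timepoints)}"
        )
    frame = _features_frame(features)
    return PatientFeatures(
        patient_id=features[0].patient_id,
        timepoint=features[0].timepoint,
        values=frame.mean(axis=0, skipna=True),
        n_per_feature=frame.notna().sum(axis=0),
        n_lesions=len(features),
    )


def percentage_change(
    var_pre: float | np.ndarray,
    var_post: float | np.ndarray,
    convention: str = AS_PRINTED,
):
    """Percentage change of a feature between baseline and post-therapy.

    Returns NaN (flagged, never +/-inf) where the baseline value is zero or
    either input is undefined.
    """
    if convention not in CONVENTIONS:
        raise AggregationError(f"unknown sign convention {convention!r}")
    pre = np.asarray(var_pre, dtype=np.float64)
    post = np.asarray(var_post, dtype=np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = 100.0 * (pre - post) / pre
    out = np.where(pre == 0, np.nan, out)
    if convention == INCREASE_POSITIVE:
        out = -out
    if np.ndim(var_pre) == 0 and np.ndim(var_post) == 0:
        return float(out)
    return out


def aggregate_delta(
    baseline: Sequence[FeatureVector],
    post: Sequence[FeatureVector],
    convention: str = AS_PRINTED,
) -> DeltaFeatures:
    """Per-lesion percentage change on matched lesion pairs, then the mean.

    Lesions are matched by ``lesion_id``; lesions present at only one
    timepoint are excluded from the delta and reported in
    ``unmatched_lesions``.
    """
    if not baseline or not post:
        raise AggregationError("both timepoints need at least one lesion")
    pre_frame = _features_frame(baseline)
    post_frame = _features_frame(post)
    matched = pre_frame.index.intersection(post_frame.index)
    unmatched = tuple(
        sorted(set(pre_frame.index).symmetric_difference(post_frame.index))
    )
    patient_id = baseline[0].patient_id
    if len(matched) == 0:
        raise AggregationError(
            f"patient {patient_id}: no lesion present at both timepoints; "
            "excluded from delta analysis"
        )
    per_lesion = pd.DataFrame(
        percentage_change(
            pre_frame.loc[matched].to_numpy(),
            post_frame.loc[matched].to_numpy(),
            convention=convention,
        ),
        index=matched,
        columns=pre_frame.columns,
    )
    values = per_lesion.mean(axis=0, skipna=True)
    values.index = ["perc_" + c for c in values.index]
    return DeltaFeatures(
        patient_id=patient_id,
        values=values,
        n_matched=len(matched),
        unmatched_lesions=unmatched,
        sign_convention=convention,
    )
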