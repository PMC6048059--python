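"""Collapse individual classifications into per-core and per-patient scores.

The core aggregate pools every response for a core across all of its
segments jointly (not segment-then-core): the proportion is the mean of
the bin midpoints over responses that indicated cancer (bin 0 contributes
0), and the intensity is the mean over responses with a positive
proportion bin.  "No cancer" responses contribute to neither mean.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .domain import BinScheme, CoreScore, classifications_to_frame, get_scheme
from .image_prep import central_segment_indices

__all__ = [
    "aggregate_core",
    "aggregate_cores",
    "aggregate_patient",
    "aggregate_patients",
    "filter_central_segments",
]

CORE_SCORE_COLUMNS = [
    "core_id",
    "marker_id",
    "proportion",
    "intensity",
    "n_responses",
    "n_cancer_responses",
    "n_intensity_responses",
    "all_no_cancer",
]


def _as_frame(classifications) -> pd.DataFrame:
    if isinstance(classifications, pd.DataFrame):
        return classifications
    return classifications_to_frame(list(classifications))


def aggregate_cores(
    classifications, scheme: int | BinScheme, marker_id: str = ""
) -> pd.DataFrame:
    """Aggregate a classification table into one row per core.

    Cores whose responses are all "no cancer" are retained with
    proportion 0, intensity 0 and ``all_no_cancer=True``.
    """
    frame = _as_frame(classifications)
    if frame.empty:
        raise ValueError("no classifications to aggregate")
    sch = get_scheme(scheme)
    midpoints = sch.midpoints

    cancer = frame["cancer_present"].to_numpy(dtype=bool)
    bins = frame["proportion_bin"].fillna(-1).to_numpy(dtype=int)
    inten = frame["intensity"].fillna(0).to_numpy(dtype=float)

    work = pd.DataFrame(
        {
            "core_id": frame["core_id"].to_numpy(),
            "is_cancer": cancer,
            "prop_value": np.where(cancer, midpoints[np.maximum(bins, 0)], 0.0),
            "has_intensity": cancer & (bins > 0),
            "int_value": np.where(cancer & (bins > 0), inten, 0.0),
        }
    )
    g = work.groupby("core_id", sort=True)
    agg = g.agg(
        n_responses=("is_cancer", "size"),
        n_cancer_responses=("is_cancer", "sum"),
        prop_sum=("prop_value", "sum"),
        n_intensity_responses=("has_intensity", "sum"),
        int_sum=("int_value", "sum"),
    ).reset_index()

    n_cancer = agg["n_cancer_responses"].to_numpy(dtype=float)
    n_int = agg["n_intensity_responses"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        proportion = np.where(n_cancer > 0, agg["prop_sum"] / n_cancer, 0.0)
        intensity = np.where(n_int > 0, agg["int_sum"] / n_int, 0.0)

    return pd.DataFrame(
        {
            "core_id": agg["core_id"],
            "marker_id": marker_id,
            "proportion": proportion,
            "intensity": intensity,
            "n_responses": agg["n_responses"].astype(int),
            "n_cancer_responses": agg["n_cancer_responses"].astype(int),
            "n_intensity_responses": agg["n_intensity_responses"].astype(int),
            "all_no_cancer": n_cancer == 0,
        }
    )


def aggregate_core(classifications, scheme: int | BinScheme, marker_id: str = "") -> CoreScore:
    """Aggregate the classifications of a single core into a CoreScore."""
    frame = _as_frame(classifications)
    if frame.empty:
        raise ValueError("no classifications to aggregate")
    if frame["core_id"].nunique() != 1:
        raise ValueError("aggregate_core expects classifications for one core")
    row = aggregate_cores(frame, scheme, marker_id).iloc[0]
    return CoreScore(
        core_id=str(row["core_id"]),
        marker_id=marker_id,
        proportion=float(row["proportion"]),
        intensity=float(row["intensity"]),
        n_responses=int(row["n_responses"]),
        n_cancer_responses=int(row["n_cancer_responses"]),
        n_intensity_responses=int(row["n_intensity_responses"]),
        all_no_cancer=bool(row["all_no_cancer"]),
    )


def aggregate_patient(core_values: pd.DataFrame) -> pd.Series:
    """Patient-level score: unweighted mean of the patient's core values.

    Expects columns ``proportion`` and ``intensity`` (typically the
    corrected per-core values); the patient H-score is recomputed from the
    patient-level means so it respects its own bounds.
    """
    if core_values.empty:
        raise ValueError("no core scores for patient")
    p = float(core_values["proportion"].mean())
    i = float(core_values["intensity"].mean())
    return pd.Series({"proportion": p, "intensity": i, "h_score": p * i})


def aggregate_patients(
    corrected: pd.DataFrame, core_map: pd.DataFrame
) -> pd.DataFrame:
    """Patient-level corrected scores for every patient in ``core_map``.

    ``corrected`` must carry core_id/marker_id plus proportion_corrected
    and intensity_corrected columns.
    """
    merged = corrected.merge(
        core_map[["core_id", "patient_id"]], on="core_id", how="inner"
    )
    g = merged.groupby(["patient_id", "marker_id"], as_index=False).agg(
        proportion=("proportion_corrected", "mean"),
        intensity=("intensity_corrected", "mean"),
        n_cores=("core_id", "size"),
    )
    g["h_score"] = g["proportion"] * g["intensity"]
    return g


def filter_central_segments(classifications):
    """Keep only classifications on the central 16 segments of the grid."""
    central = central_segment_indices()
    if isinstance(classifications, pd.DataFrame):
        return classifications[
            classifications["segment_index"].isin(central)
        ].reset_index(drop=True)
    central_set = set(central)
    return [c for c in classifications if c.segment_index in central_set]
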