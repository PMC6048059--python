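"""Linear bias correction of aggregated scores against expert gold standard.

Averaging bounded noisy scores biases the aggregate towards the middle of
the range: a core with a true proportion of 0 can only be overestimated.
The remedy is a per-marker linear map from the crowd scale to the expert
scale, with clipping at the score bounds.  Cores that themselves carry an
expert score are corrected with k-fold cross-validated predictions so
their own expert value never leaks into their correction; all remaining
cores use the model fitted on every expert-scored core.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LinearRegression

from .domain import INTENSITY_BOUNDS, PROPORTION_BOUNDS

__all__ = [
    "LinearCorrection",
    "fit_correction",
    "apply_correction",
    "assign_folds",
    "cv_correct_expert_cores",
    "correct_all",
    "h_score",
]

CORRECTED_COLUMNS = [
    "core_id",
    "marker_id",
    "proportion_corrected",
    "intensity_corrected",
    "h_score",
    "clipped_proportion",
    "clipped_intensity",
    "was_cv",
]


@dataclass(frozen=True)
class LinearCorrection:
    """A fitted crowd -> expert linear map with clipping bounds."""

    target: str  # "proportion" or "intensity"
    intercept: float
    slope: float
    lower_bound: float
    upper_bound: float
    n_fit: int


def fit_correction(
    crowd_values,
    expert_values,
    bounds: tuple[float, float] = PROPORTION_BOUNDS,
    target: str = "proportion",
) -> LinearCorrection:
    """Ordinary least squares of expert on crowd values.

    The regression maps the crowd scale onto the expert (gold-standard)
    scale; predictions are later clipped into ``bounds``.
    """
    x = np.asarray(crowd_values, dtype=float)
    y = np.asarray(expert_values, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("crowd and expert values must be 1-D and paired")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs to fit a correction")
    if np.ptp(x) == 0:
        raise ValueError("crowd values are constant; correction is degenerate")
    model = LinearRegression().fit(x[:, None], y)
    return LinearCorrection(
        target=target,
        intercept=float(model.intercept_),
        slope=float(model.coef_[0]),
        lower_bound=float(bounds[0]),
        upper_bound=float(bounds[1]),
        n_fit=len(x),
    )


def apply_correction(value, correction: LinearCorrection):
    """Apply ``intercept + slope * value`` then clip into the bounds.

    Returns ``(corrected, clipped)`` with the same shape as the input;
    scalars in, scalars out.
    """
    v = np.asarray(value, dtype=float)
    raw = correction.intercept + correction.slope * v
    # round away sub-1e-10 dust so exact ties survive the affine map
    # (rank statistics downstream are sensitive to epsilon tie-breaking)
    raw = np.round(raw, 10)
    clipped_flag = (raw < correction.lower_bound) | (raw > correction.upper_bound)
    out = np.clip(raw, correction.lower_bound, correction.upper_bound)
    if np.isscalar(value) or v.ndim == 0:
        return float(out), bool(clipped_flag)
    return out, clipped_flag


def assign_folds(n: int, k_folds: int, seed: int) -> np.ndarray:
    """Fold label per index: a seeded uniform permutation split into k
    contiguous blocks (sizes differing by at most one)."""
    if not 2 <= k_folds <= n:
        raise ValueError(f"need 2 <= k_folds <= n, got k={k_folds}, n={n}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    perm = rng.permutation(n)
    labels = np.empty(n, dtype=int)
    for fold, block in enumerate(np.array_split(perm, k_folds)):
        labels[block] = fold
    return labels


def cv_correct_expert_cores(
    crowd_values,
    expert_values,
    bounds: tuple[float, float] = PROPORTION_BOUNDS,
    k_folds: int = 10,
    seed: int = 0,
    target: str = "proportion",
    folds: np.ndarray | None = None,
):
    """Leakage-free corrected values for the expert-scored cores.

    Each core's corrected value is predicted (and clipped) by a model
    fitted on the other k-1 folds, so no core's own expert score ever
    influences its own correction.  Returns ``(corrected, clipped)``.
    """
    x = np.asarray(crowd_values, dtype=float)
    y = np.asarray(expert_values, dtype=float)
    n = len(x)
    if folds is None:
        folds = assign_folds(n, k_folds, seed)
    folds = np.asarray(folds)
    out = np.empty(n)
    clipped = np.zeros(n, dtype=bool)
    for fold in np.unique(folds):
        held = folds == fold
        model = fit_correction(x[~held], y[~held], bounds=bounds, target=target)
        out[held], clipped[held] = apply_correction(x[held], model)
    return out, clipped


def h_score(proportion: float, intensity: float) -> float:
    """H-score: proportion of stained cancer cells (0-100) times mean
    staining intensity (0-3); ranges over [0, 300]."""
    p = np.asarray(proportion, dtype=float)
    i = np.asarray(intensity, dtype=float)
    if np.any((p < 0) | (p > 100)):
        raise ValueError("proportion must lie in [0, 100]")
    if np.any((i < 0) | (i > 3)):
        raise ValueError("intensity must lie in [0, 3]")
    out = p * i
    return float(out) if out.ndim == 0 else out


def correct_all(
    core_scores: pd.DataFrame,
    expert_scores: pd.DataFrame,
    k_folds: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Correct every core score against the expert gold standard.

    Proportion and intensity are corrected by separate linear models per
    marker.  Expert-scored cores receive cross-validated predictions
    (``was_cv=True``); all other cores use the full-data fit.
    """
    if expert_scores.empty:
        raise ValueError("expert score set is empty; cannot fit a correction")
    pieces = []
    for marker, scores in core_scores.groupby("marker_id", sort=True):
        experts = expert_scores[expert_scores["marker_id"] == marker]
        paired = scores.merge(
            experts[["core_id", "proportion", "intensity"]],
            on="core_id",
            suffixes=("", "_expert"),
            how="inner",
        )
        if paired.empty:
            raise ValueError(f"marker {marker!r} has no expert-scored cores")
        n_exp = len(paired)
        if n_exp < k_folds:
            raise ValueError(
                f"marker {marker!r}: {n_exp} expert cores < k_folds={k_folds}"
            )

        specs = {
            "proportion": PROPORTION_BOUNDS,
            "intensity": INTENSITY_BOUNDS,
        }
        full_models = {
            t: fit_correction(
                paired[t], paired[f"{t}_expert"], bounds=b, target=t
            )
            for t, b in specs.items()
        }

        expert_ids = set(paired["core_id"])
        is_expert = scores["core_id"].isin(expert_ids).to_numpy()
        out = scores[["core_id", "marker_id"]].copy()
        folds = assign_folds(n_exp, k_folds, seed)
        cv_by_core = {}
        for t, b in specs.items():
            cv_vals, cv_clip = cv_correct_expert_cores(
                paired[t],
                paired[f"{t}_expert"],
                bounds=b,
                k_folds=k_folds,
                target=t,
                folds=folds,
            )
            cv_by_core[t] = dict(zip(paired["core_id"], zip(cv_vals, cv_clip)))

        corrected = {}
        for t in specs:
            vals, clips = apply_correction(
                scores[t].to_numpy(), full_models[t]
            )
            cv_map = cv_by_core[t]
            for pos, (cid, exp_flag) in enumerate(
                zip(scores["core_id"], is_expert)
            ):
                if exp_flag:
                    vals[pos], clips[pos] = cv_map[cid]
            corrected[t] = (vals, clips)

        out["proportion_corrected"] = corrected["proportion"][0]
        out["intensity_corrected"] = corrected["intensity"][0]
        out["h_score"] = h_score(
            out["proportion_corrected"].to_numpy(),
            out["intensity_corrected"].to_numpy(),
        )
        out["clipped_proportion"] = corrected["proportion"][1]
        out["clipped_intensity"] = corrected["intensity"][1]
        out["was_cv"] = is_expert
        pieces.append(out)
    return pd.concat(pieces, ignore_index=True)
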