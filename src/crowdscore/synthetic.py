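"""Ground-truthed synthetic crowds.

Generates cores with known staining truth, per-segment cancer content,
noisy citizen classifications under the conditional-questioning task,
low-noise expert scores, and patient survival whose log-hazard is linear
in the true H-score.  Every downstream stage of the pipeline can then be
tested by parameter recovery.

All generators are deterministic given their integer seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .domain import COHORTS, BinScheme, get_scheme, validate_frame
from .image_prep import N_SEGMENTS, central_segment_indices

__all__ = [
    "TrueCore",
    "RaterModel",
    "SurvivalModel",
    "generate_cores",
    "generate_classifications",
    "generate_expert_scores",
    "generate_survival",
    "truth_frame",
    "core_map_frame",
    "patient_true_h",
]


@dataclass
class TrueCore:
    core_id: str
    patient_id: str
    marker_id: str
    true_proportion: float  # percent of cancer cells stained, 0-100
    true_intensity: float  # continuous staining intensity, 0-3
    segment_cancer_fraction: np.ndarray  # length 36, fraction of cancer tissue

    @property
    def true_h(self) -> float:
        return self.true_proportion * self.true_intensity


@dataclass
class RaterModel:
    """Error model for a single anonymous rater.

    A rater misses cancer on a cancer-bearing segment with probability
    ``p_miss_cancer`` and claims cancer on an empty segment with
    probability ``p_false_cancer``.  Conditional on reporting cancer, the
    reported proportion is the core truth plus Gaussian noise (clipped to
    [0, 100], then censored into the scheme's bins) and the reported
    intensity is the truth plus Gaussian noise rounded into {1, 2, 3}.
    """

    p_miss_cancer: float = 0.10
    p_false_cancer: float = 0.05
    proportion_noise_sd: float = 15.0
    intensity_noise_sd: float = 0.5

    def __post_init__(self) -> None:
        for p in (self.p_miss_cancer, self.p_false_cancer):
            if not 0 <= p <= 1:
                raise ValueError("error probabilities must lie in [0, 1]")
        if self.proportion_noise_sd < 0 or self.intensity_noise_sd < 0:
            raise ValueError("noise SDs must be non-negative")


@dataclass
class SurvivalModel:
    """Exponential event times with log-hazard linear in the H-score."""

    baseline_rate: float = 0.02  # events per month at H-score 0
    beta_h: float = math.log(0.991)  # log-hazard per unit H-score
    censor_rate: float = 0.005  # independent exponential censoring

    def __post_init__(self) -> None:
        if self.baseline_rate <= 0 or self.censor_rate <= 0:
            raise ValueError("baseline_rate and censor_rate must be positive")


# Mixture prior for the true proportion: mass at exactly 0, a uniform body,
# and mass near 100, so the boundary-bias machinery is exercised at both ends.
_P_ZERO = 0.25
_P_HIGH = 0.25
_HIGH_LOW = 95.0

# Per-segment cancer content: central 16 segments from a high-mean Beta,
# outer 20 from a low-mean Beta with a point mass at zero (empty segments).
_CENTRAL_BETA = (5.0, 2.0)
_OUTER_BETA = (1.2, 4.0)
_OUTER_EMPTY_P = 0.5


def true_proportion_mixture_moments() -> tuple[float, float]:
    """Closed-form (mean, variance) of the true-proportion prior."""
    p_body = 1.0 - _P_ZERO - _P_HIGH
    m_body, m_high = 50.0, (_HIGH_LOW + 100.0) / 2.0
    mean = p_body * m_body + _P_HIGH * m_high
    ex2_body = 100.0**2 / 3.0
    ex2_high = (_HIGH_LOW**2 + _HIGH_LOW * 100.0 + 100.0**2) / 3.0
    ex2 = p_body * ex2_body + _P_HIGH * ex2_high
    return mean, ex2 - mean**2


def generate_cores(
    n_patients: int,
    cores_per_patient: int,
    marker_id: str = "M1",
    seed: int = 0,
) -> list[TrueCore]:
    """Draw ground-truth cores for ``n_patients`` patients."""
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    if not 1 <= cores_per_patient <= 5:
        raise ValueError("cores_per_patient must be in 1..5")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n_cores = n_patients * cores_per_patient
    comp = rng.random(n_cores)
    prop = rng.uniform(0.0, 100.0, n_cores)
    prop[comp < _P_ZERO] = 0.0
    high = comp >= 1.0 - _P_HIGH
    prop[high] = rng.uniform(_HIGH_LOW, 100.0, int(high.sum()))
    intensity = rng.uniform(0.5, 3.0, n_cores)
    intensity[prop == 0] = 0.0  # nothing stains: staining intensity is 0

    central = set(central_segment_indices())
    cores = []
    for i in range(n_cores):
        patient_idx = i // cores_per_patient
        frac = np.empty(N_SEGMENTS)
        for s in range(N_SEGMENTS):
            if s in central:
                frac[s] = rng.beta(*_CENTRAL_BETA)
            else:
                frac[s] = 0.0 if rng.random() < _OUTER_EMPTY_P else rng.beta(
                    *_OUTER_BETA
                )
        cores.append(
            TrueCore(
                core_id=f"c{i:05d}",
                patient_id=f"p{patient_idx:05d}",
                marker_id=marker_id,
                true_proportion=float(prop[i]),
                true_intensity=float(intensity[i]),
                segment_cancer_fraction=frac,
            )
        )
    return cores


def generate_classifications(
    cores: list[TrueCore],
    raters_per_segment: int,
    rater_model: RaterModel | None = None,
    scheme: int | BinScheme = 1,
    central_only: bool = True,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate the crowd: ``raters_per_segment`` independent responses for
    every scored segment of every core.

    Returns the canonical classification DataFrame (validated).
    """
    if raters_per_segment < 1:
        raise ValueError("raters_per_segment must be >= 1")
    model = rater_model or RaterModel()
    sch = get_scheme(scheme)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    segs = np.asarray(
        central_segment_indices() if central_only else range(N_SEGMENTS)
    )

    core_ids, seg_idx, cancer_col, bin_col, int_col = [], [], [], [], []
    for core in cores:
        n = len(segs) * raters_per_segment
        frac = np.repeat(core.segment_cancer_fraction[segs], raters_per_segment)
        u = rng.random(n)
        reports_cancer = np.where(
            frac > 0, u >= model.p_miss_cancer, u < model.p_false_cancer
        )
        prop_raw = np.clip(
            core.true_proportion + rng.normal(0.0, model.proportion_noise_sd, n)
            if model.proportion_noise_sd > 0
            else np.full(n, core.true_proportion),
            0.0,
            100.0,
        )
        bins = sch.censor(prop_raw)
        inten_raw = core.true_intensity + (
            rng.normal(0.0, model.intensity_noise_sd, n)
            if model.intensity_noise_sd > 0
            else 0.0
        )
        inten = np.clip(np.rint(inten_raw), 1, 3).astype(int)

        core_ids.append(np.full(n, core.core_id, dtype=object))
        seg_idx.append(np.repeat(segs, raters_per_segment))
        cancer_col.append(reports_cancer)
        bin_col.append(np.where(reports_cancer, bins, -1))
        int_col.append(np.where(reports_cancer & (bins > 0), inten, -1))

    bins_all = np.concatenate(bin_col)
    ints_all = np.concatenate(int_col)
    frame = pd.DataFrame(
        {
            "core_id": np.concatenate(core_ids),
            "segment_index": np.concatenate(seg_idx).astype(int),
            "cancer_present": np.concatenate(cancer_col),
            "proportion_bin": pd.array(
                np.where(bins_all < 0, None, bins_all), dtype="Int64"
            ),
            "intensity": pd.array(
                np.where(ints_all < 0, None, ints_all), dtype="Int64"
            ),
        }
    )
    validate_frame(frame)
    return frame


def generate_expert_scores(
    cores: list[TrueCore],
    expert_fraction: float,
    expert_noise_sd: float = 2.0,
    seed: int = 0,
    scheme: int | BinScheme | None = None,
) -> pd.DataFrame:
    """Score a simple random subset of cores with low-noise observations of
    the truth.  The subset size is round-half-up(expert_fraction * n).

    By default experts score continuously; pass ``scheme`` to have them
    report proportions as bin midpoints of that scheme and intensities
    rounded to whole categories (whether the study's experts scored
    continuously or in bins is not recorded)."""
    if not cores:
        raise ValueError("empty core list")
    if not 0 < expert_fraction <= 1:
        raise ValueError("expert_fraction must be in (0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n_sel = int(math.floor(expert_fraction * len(cores) + 0.5))
    n_sel = max(1, n_sel)
    chosen = rng.choice(len(cores), size=n_sel, replace=False)
    chosen.sort()
    rows = []
    for i in chosen:
        core = cores[i]
        prop = core.true_proportion
        inten = core.true_intensity
        if expert_noise_sd > 0:
            prop += rng.normal(0.0, expert_noise_sd)
            # intensity noise on its own 0-3 scale, proportional to the
            # proportion noise relative to the 0-100 range
            inten += rng.normal(0.0, expert_noise_sd * 3.0 / 100.0)
        prop = float(np.clip(prop, 0.0, 100.0))
        inten = float(np.clip(inten, 0.0, 3.0))
        if scheme is not None:
            sch = get_scheme(scheme)
            prop = sch.midpoint(int(sch.censor(prop)))
            inten = float(np.clip(np.floor(inten + 0.5), 0, 3))
        rows.append((core.core_id, core.marker_id, prop, inten))
    return pd.DataFrame(
        rows, columns=["core_id", "marker_id", "proportion", "intensity"]
    )


def truth_frame(cores: list[TrueCore]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "core_id": [c.core_id for c in cores],
            "true_proportion": [c.true_proportion for c in cores],
            "true_intensity": [c.true_intensity for c in cores],
            "true_h": [c.true_h for c in cores],
        }
    )


def core_map_frame(cores: list[TrueCore]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "core_id": [c.core_id for c in cores],
            "patient_id": [c.patient_id for c in cores],
            "marker_id": [c.marker_id for c in cores],
        }
    )


def patient_true_h(cores: list[TrueCore]) -> pd.DataFrame:
    """Patient-level true H-score: the mean of the patient's core truths."""
    df = pd.DataFrame(
        {
            "patient_id": [c.patient_id for c in cores],
            "true_h": [c.true_h for c in cores],
        }
    )
    return df.groupby("patient_id", as_index=False)["true_h"].mean()


def generate_survival(
    patients_with_true_h: pd.DataFrame,
    survival_model: SurvivalModel | None = None,
    seed: int = 0,
    h_column: str = "true_h",
) -> pd.DataFrame:
    """Simulate outcome rows: exponential event times with hazard
    ``baseline_rate * exp(beta_h * h)`` and independent exponential
    censoring, plus clinical covariates drawn independently of outcome."""
    model = survival_model or SurvivalModel()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    h = patients_with_true_h[h_column].to_numpy(dtype=float)
    n = len(h)
    if n == 0:
        raise ValueError("no patients supplied")
    rate = model.baseline_rate * np.exp(model.beta_h * h)
    t_event = rng.exponential(1.0 / rate)
    t_cens = rng.exponential(1.0 / model.censor_rate, n)
    time = np.maximum(np.minimum(t_event, t_cens), 1e-9)
    event = t_event <= t_cens
    return pd.DataFrame(
        {
            "patient_id": patients_with_true_h["patient_id"].to_numpy(),
            "cohort": rng.choice(COHORTS, size=n, p=(0.4, 0.3, 0.3)),
            "time_months": time,
            "event": event,
            "age": np.round(rng.normal(70.0, 8.0, n), 1),
            "t_stage": rng.integers(1, 5, n),
            "n_stage": rng.integers(0, 3, n),
            "grade": rng.integers(1, 4, n),
            "sex": rng.choice(["M", "F"], size=n, p=(0.75, 0.25)),
            "hydronephrosis": rng.random(n) < 0.2,
        }
    )
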