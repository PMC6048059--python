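"""Crowd-vs-expert agreement statistics with percentile-bootstrap CIs."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .domain import AgreementResult

__all__ = [
    "spearman_rho",
    "confusion_matrix",
    "kappa_from_confusion",
    "quadratic_weighted_kappa",
    "discretize_intensity",
    "bootstrap_ci",
    "agreement_table",
]


def spearman_rho(x, y) -> float:
    """Spearman rank correlation (mid-ranks for ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or len(x) < 3:
        raise ValueError("need paired inputs with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman undefined for constant input")
    return float(stats.spearmanr(x, y).statistic)


def confusion_matrix(ratings_a, ratings_b, n_categories: int) -> np.ndarray:
    a = np.asarray(ratings_a, dtype=int)
    b = np.asarray(ratings_b, dtype=int)
    if a.shape != b.shape or len(a) < 2:
        raise ValueError("need paired ratings with n >= 2")
    if a.min() < 0 or b.min() < 0 or a.max() >= n_categories or b.max() >= n_categories:
        raise ValueError("ratings outside category range")
    return np.bincount(
        a * n_categories + b, minlength=n_categories * n_categories
    ).reshape(n_categories, n_categories)


def kappa_from_confusion(matrix) -> float:
    """Quadratic-weighted kappa from a square confusion matrix.

    kappa = 1 - sum(w * O) / sum(w * E) with weights
    w[i, j] = (i - j)^2 / (k - 1)^2, O the observed matrix and E the outer
    product of the marginals scaled to the same total.  If the expected
    weighted disagreement is zero (both raters constant on the same
    category) the ratings agree perfectly and kappa is 1.
    """
    o = np.asarray(matrix, dtype=float)
    k = o.shape[0]
    if o.ndim != 2 or o.shape[1] != k:
        raise ValueError("confusion matrix must be square")
    n = o.sum()
    if n <= 0:
        raise ValueError("empty confusion matrix")
    idx = np.arange(k)
    w = (idx[:, None] - idx[None, :]) ** 2 / (k - 1) ** 2
    e = np.outer(o.sum(axis=1), o.sum(axis=0)) / n
    denom = float((w * e).sum())
    if denom == 0.0:
        return 1.0
    return 1.0 - float((w * o).sum()) / denom


def quadratic_weighted_kappa(ratings_a, ratings_b, n_categories: int = 4) -> float:
    """Quadratic-weighted Cohen kappa between two ordinal rating vectors."""
    return kappa_from_confusion(
        confusion_matrix(ratings_a, ratings_b, n_categories)
    )


def discretize_intensity(continuous_intensity):
    """Round a continuous 0-3 intensity half-up to an ordinal in {0,1,2,3}."""
    v = np.asarray(continuous_intensity, dtype=float)
    if np.any((v < 0) | (v > 3)):
        raise ValueError("intensity must lie in [0, 3]")
    out = np.clip(np.floor(v + 0.5), 0, 3).astype(int)
    return int(out) if out.ndim == 0 else out


def bootstrap_ci(
    paired_data,
    statistic,
    n_boot: int = 1000,
    seed: int = 0,
    ci: float = 95.0,
) -> tuple[float, float, float]:
    """Percentile bootstrap over pairs.

    ``paired_data`` is an (x, y) tuple of equal-length arrays; ``statistic``
    is a callable of (x, y).  The point estimate is the statistic on the
    full data; the CI is the empirical 2.5/97.5 percentile (for ci=95) of
    the statistic over ``n_boot`` resamples of pairs with replacement.
    """
    x, y = (np.asarray(a) for a in paired_data)
    n = len(x)
    if n < 10:
        raise ValueError("need at least 10 pairs to bootstrap")
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    estimate = float(statistic(x, y))
    if not isinstance(seed, np.random.SeedSequence):
        seed = np.random.SeedSequence(seed)
    rng = np.random.default_rng(seed)
    reps = np.full(n_boot, np.nan)
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        try:
            reps[b] = statistic(x[idx], y[idx])
        except ValueError:
            continue
    ok = np.isfinite(reps)
    if ok.sum() <= n_boot / 2:
        raise ValueError("statistic undefined on more than half the resamples")
    lo_q, hi_q = (100.0 - ci) / 2.0, 100.0 - (100.0 - ci) / 2.0
    lo, hi = np.percentile(reps[ok], [lo_q, hi_q])
    return estimate, float(min(lo, estimate)), float(max(hi, estimate))


def agreement_table(
    corrected_scores: pd.DataFrame,
    expert_scores: pd.DataFrame,
    markers=None,
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-marker crowd-vs-expert agreement over expert-scored cores.

    Spearman rho for H-score and proportion; quadratic-weighted kappa for
    intensity discretised to {0,1,2,3}; each with a bootstrap 95% CI.
    """
    if markers is None:
        markers = sorted(expert_scores["marker_id"].unique())
    rows = []
    ss = np.random.SeedSequence(seed)
    for marker, sub_ss in zip(markers, ss.spawn(len(markers))):
        crowd = corrected_scores[corrected_scores["marker_id"] == marker]
        expert = expert_scores[expert_scores["marker_id"] == marker]
        paired = crowd.merge(
            expert[["core_id", "proportion", "intensity"]],
            on="core_id",
            how="inner",
        )
        if len(paired) < 10:
            raise ValueError(f"marker {marker!r}: fewer than 10 expert pairs")
        expert_h = paired["proportion"].to_numpy() * paired["intensity"].to_numpy()
        comparisons = {
            "spearman_h": (
                paired["h_score"].to_numpy(),
                expert_h,
                spearman_rho,
            ),
            "spearman_proportion": (
                paired["proportion_corrected"].to_numpy(),
                paired["proportion"].to_numpy(),
                spearman_rho,
            ),
            "qw_kappa_intensity": (
                discretize_intensity(paired["intensity_corrected"].to_numpy()),
                discretize_intensity(paired["intensity"].to_numpy()),
                lambda a, b: quadratic_weighted_kappa(a, b, 4),
            ),
        }
        for (metric, (a, b, fn)), stat_seed in zip(
            comparisons.items(), sub_ss.spawn(len(comparisons))
        ):
            est, lo, hi = bootstrap_ci((a, b), fn, n_boot=n_boot, seed=stat_seed)
            result = AgreementResult(
                metric=metric,
                estimate=est,
                ci_low=lo,
                ci_high=hi,
                n_pairs=len(paired),
                n_bootstrap=n_boot,
            )
            rows.append(
                {
                    "marker_id": marker,
                    "metric": result.metric,
                    "estimate": result.estimate,
                    "ci_low": result.ci_low,
                    "ci_high": result.ci_high,
                    "n_pairs": result.n_pairs,
                }
            )
    return pd.DataFrame(rows)
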