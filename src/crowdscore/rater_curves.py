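"""Accuracy as a function of the number of classifications per core.

Subsamples the classification pool per core, re-runs aggregation and
correction, and measures crowd-vs-expert Spearman agreement on H-scores.
Bootstrap error bars resample the subsampling randomness and the
expert-core pairing jointly (95% CI from the 2.5/97.5 percentiles).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .agreement import spearman_rho
from .aggregation import aggregate_cores
from .correction import correct_all
from .domain import BinScheme, get_scheme

__all__ = ["subsample_classifications", "accuracy_curve", "plot_curve"]


def subsample_classifications(
    classifications: pd.DataFrame,
    n_per_core: int,
    seed: int | np.random.SeedSequence = 0,
    on_insufficient: str = "skip",
) -> pd.DataFrame:
    """Uniform random subset of exactly ``n_per_core`` classifications per
    core, without replacement.

    Cores with fewer classifications are skipped (default) or raise, per
    ``on_insufficient`` in {"skip", "error"}.
    """
    if n_per_core < 1:
        raise ValueError("n_per_core must be >= 1")
    if not isinstance(seed, np.random.SeedSequence):
        seed = np.random.SeedSequence(seed)
    rng = np.random.default_rng(seed)
    counts = classifications.groupby("core_id")["core_id"].transform("size")
    if on_insufficient == "error" and (counts < n_per_core).any():
        short = classifications.loc[counts < n_per_core, "core_id"].unique()
        raise ValueError(
            f"cores with fewer than {n_per_core} classifications: {list(short[:5])}"
        )
    eligible = classifications[counts >= n_per_core]
    key = rng.random(len(eligible))
    shuffled = eligible.iloc[np.argsort(key, kind="stable")]
    out = shuffled.groupby("core_id", sort=False).head(n_per_core)
    return out.sort_index().reset_index(drop=True)


def _spearman_pass(
    classifications: pd.DataFrame,
    expert_scores: pd.DataFrame,
    scheme: BinScheme,
    n_per_core: int,
    sub_seed: np.random.SeedSequence,
    k_folds: int,
    marker_id: str,
    pair_idx: np.ndarray | None = None,
) -> float:
    """One subsample -> aggregate -> correct -> Spearman evaluation."""
    sub = subsample_classifications(classifications, n_per_core, seed=sub_seed)
    scores = aggregate_cores(sub, scheme, marker_id=marker_id)
    corrected = correct_all(scores, expert_scores, k_folds=k_folds)
    paired = corrected.merge(
        expert_scores[["core_id", "proportion", "intensity"]],
        on="core_id",
        how="inner",
    )
    crowd_h = paired["h_score"].to_numpy()
    expert_h = paired["proportion"].to_numpy() * paired["intensity"].to_numpy()
    if pair_idx is not None:
        pair_idx = pair_idx[pair_idx < len(paired)]
        crowd_h, expert_h = crowd_h[pair_idx], expert_h[pair_idx]
    return spearman_rho(crowd_h, expert_h)


def accuracy_curve(
    classifications: pd.DataFrame,
    expert_scores: pd.DataFrame,
    scheme: int | BinScheme,
    n_values=(20, 40, 80, 160, 320, 640, 1280),
    n_boot: int = 1000,
    seed: int = 0,
    k_folds: int = 10,
    marker_id: str | None = None,
) -> pd.DataFrame:
    """H-score Spearman agreement vs classifications per core.

    Returns one row per n: (marker_id, n_per_core, estimate, ci_low,
    ci_high, n_boot).  Cores with fewer than n classifications are
    dropped for that n.
    """
    sch = get_scheme(scheme)
    if marker_id is None:
        markers = expert_scores["marker_id"].unique()
        if len(markers) != 1:
            raise ValueError("pass marker_id when experts cover several markers")
        marker_id = str(markers[0])
    n_values = sorted(int(n) for n in n_values)
    n_expert = len(
        set(classifications["core_id"]) & set(expert_scores["core_id"])
    )
    if n_expert < 10:
        raise ValueError("need at least 10 expert-scored cores with responses")
    root = np.random.SeedSequence(seed)
    rows = []
    for n, n_ss in zip(n_values, root.spawn(len(n_values))):
        est_ss, boot_ss = n_ss.spawn(2)
        estimate = _spearman_pass(
            classifications, expert_scores, sch, n, est_ss, k_folds, marker_id
        )
        boot_children = boot_ss.spawn(n_boot)
        pair_rng = np.random.default_rng(boot_ss)
        reps = np.full(n_boot, np.nan)
        for b in range(n_boot):
            idx = pair_rng.integers(0, n_expert, n_expert)
            try:
                reps[b] = _spearman_pass(
                    classifications,
                    expert_scores,
                    sch,
                    n,
                    boot_children[b],
                    k_folds,
                    marker_id,
                    pair_idx=idx,
                )
            except ValueError:
                continue
        ok = np.isfinite(reps)
        if ok.sum() < n_boot / 2:
            raise ValueError(f"bootstrap failed for n_per_core={n}")
        lo, hi = np.percentile(reps[ok], [2.5, 97.5])
        rows.append(
            {
                "marker_id": marker_id,
                "n_per_core": n,
                "estimate": estimate,
                "ci_low": float(lo),
                "ci_high": float(hi),
                "boot_mean": float(reps[ok].mean()),
                "boot_sd": float(reps[ok].std(ddof=1)),
                "n_boot": int(ok.sum()),
            }
        )
    return pd.DataFrame(rows)


def plot_curve(curve: pd.DataFrame, path) -> None:
    """Write a PNG of the accuracy curve with bootstrap error bars."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    est = curve["estimate"]
    ax.errorbar(
        curve["n_per_core"],
        est,
        yerr=[est - curve["ci_low"], curve["ci_high"] - est],
        fmt="o-",
        capsize=3,
    )
    ax.set_xscale("log")
    ax.set_xlabel("classifications per core")
    ax.set_ylabel("H-score Spearman rho vs experts")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
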