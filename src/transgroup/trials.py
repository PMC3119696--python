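"""Trial censoring and stimulus-set screening.

Two censoring stages clean a trial table before analysis:

1. *saccade execution*: trials whose main saccade landed more than 1.5
   degrees from the stimulus center, or lasted longer than 85 ms, are
   removed (the saccade itself was anomalous);
2. *target localization*: trials with more than two additional
   target-directed saccades, or exactly two and a final fixation duration
   at or above the cutoff (default 240 ms), are removed (the subject had
   trouble finding the target).  Trials with exactly two additional
   saccades but a short final fixation are kept — they generated the
   response without actually needing the second additional saccade.

Boundary semantics are deliberate: strictly greater for the landing,
duration and saccade-count rules; greater-or-equal for the fixation rule.
Both stages are idempotent and order-invariant.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

LANDING_CUTOFF_DEG = 1.5
DURATION_CUTOFF_MS = 85.0
MAX_EXTRA_SACCADES = 2
FIXATION_CUTOFF_MS = 240.0


@dataclass
class CensorReport:
    """Accounting for one (or both) censoring stages."""

    n_input: int
    n_removed_landing: int = 0
    n_removed_duration: int = 0
    n_removed_extra_saccades: int = 0
    n_removed_slow_second_fixation: int = 0
    n_retained: int = 0
    condition_proportions: dict = field(default_factory=dict)

    @property
    def n_removed(self) -> int:
        return (
            self.n_removed_landing
            + self.n_removed_duration
            + self.n_removed_extra_saccades
            + self.n_removed_slow_second_fixation
        )

    @property
    def retained_fraction(self) -> float:
        return self.n_retained / self.n_input if self.n_input else float("nan")

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_removed_landing": self.n_removed_landing,
            "n_removed_duration": self.n_removed_duration,
            "n_removed_extra_saccades": self.n_removed_extra_saccades,
            "n_removed_slow_second_fixation": self.n_removed_slow_second_fixation,
            "n_retained": self.n_retained,
            "retained_fraction": self.retained_fraction,
            "condition_proportions": self.condition_proportions,
        }


def _proportions(df: pd.DataFrame) -> dict:
    if len(df) == 0 or "condition" not in df.columns:
        return {}
    return df["condition"].value_counts(normalize=True).to_dict()


def _require(df: pd.DataFrame, *cols: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise KeyError(f"trial table is missing required column(s) {missing}")


def landing_distance(df: pd.DataFrame) -> np.ndarray:
    """Euclidean landing distance from the display center, degrees."""
    _require(df, "landing_x_deg", "landing_y_deg")
    return np.hypot(df["landing_x_deg"].to_numpy(), df["landing_y_deg"].to_numpy())


def censor_saccade_execution(
    trials: pd.DataFrame,
    landing_cutoff: float = LANDING_CUTOFF_DEG,
    duration_cutoff: float = DURATION_CUTOFF_MS,
) -> tuple[pd.DataFrame, CensorReport]:
    """Remove trials with inaccurate (> cutoff degrees) or overlong saccades."""
    _require(trials, "landing_x_deg", "landing_y_deg", "saccade_duration_ms")
    report = CensorReport(n_input=len(trials))
    if len(trials) == 0:
        return trials.copy(), report
    bad_landing = landing_distance(trials) > landing_cutoff
    bad_duration = trials["saccade_duration_ms"].to_numpy() > duration_cutoff
    report.n_removed_landing = int(bad_landing.sum())
    report.n_removed_duration = int((bad_duration & ~bad_landing).sum())
    retained = trials.loc[~(bad_landing | bad_duration)].copy()
    report.n_retained = len(retained)
    report.condition_proportions = _proportions(retained)
    return retained, report


def censor_target_localization(
    trials: pd.DataFrame,
    fixation_cutoff_ms: float = FIXATION_CUTOFF_MS,
    max_extra: int = MAX_EXTRA_SACCADES,
) -> tuple[pd.DataFrame, CensorReport]:
    """Remove trials where locating the target apparently was difficult."""
    _require(trials, "n_additional_saccades", "final_fixation_ms")
    report = CensorReport(n_input=len(trials))
    if len(trials) == 0:
        return trials.copy(), report
    extra = trials["n_additional_saccades"].to_numpy()
    if np.any(extra < 0):
        raise ValueError("negative additional-saccade counts")
    fix = trials["final_fixation_ms"].to_numpy()
    too_many = extra > max_extra
    slow_second = (extra == max_extra) & (fix >= fixation_cutoff_ms)
    report.n_removed_extra_saccades = int(too_many.sum())
    report.n_removed_slow_second_fixation = int(slow_second.sum())
    retained = trials.loc[~(too_many | slow_second)].copy()
    report.n_retained = len(retained)
    report.condition_proportions = _proportions(retained)
    return retained, report


def censor_trials(
    trials: pd.DataFrame, fixation_cutoff_ms: float = FIXATION_CUTOFF_MS
) -> tuple[pd.DataFrame, CensorReport]:
    """Apply both censoring stages; counts are against the full input."""
    step1, rep1 = censor_saccade_execution(trials)
    step2, rep2 = censor_target_localization(step1, fixation_cutoff_ms)
    report = CensorReport(
        n_input=len(trials),
        n_removed_landing=rep1.n_removed_landing,
        n_removed_duration=rep1.n_removed_duration,
        n_removed_extra_saccades=rep2.n_removed_extra_saccades,
        n_removed_slow_second_fixation=rep2.n_removed_slow_second_fixation,
        n_retained=len(step2),
        condition_proportions=_proportions(step2),
    )
    return step2, report


def derive_fixation_cutoff(trials: pd.DataFrame) -> float:
    """Estimate the final-fixation cutoff separating anticipated responses.

    Trials with exactly two additional saccades whose final fixation was
    short are assumed to behave like one-additional-saccade trials (the
    response was generated without needing the second saccade); slower
    final fixations mark genuinely slow trials.  The cutoff is fit as an
    anchored two-piece L1 changepoint over the observed fixation durations
    of the two-saccade trials: the fast piece is anchored at the median RT
    of one-additional-saccade trials and the slow piece at its own median;
    the returned cutoff minimizes the summed absolute deviations (ties go
    to the smallest cutoff).  Under homogeneous data this collapses to the
    smallest observed fixation duration.
    """
    _require(trials, "n_additional_saccades", "final_fixation_ms", "rt_ms")
    one = trials.loc[trials["n_additional_saccades"] == 1, "rt_ms"].to_numpy()
    two = trials.loc[trials["n_additional_saccades"] == 2]
    if len(two) == 0:
        raise ValueError("no trials with exactly two additional saccades")
    if len(one) == 0:
        raise ValueError("no trials with exactly one additional saccade")
    m1 = float(np.median(one))
    order = np.argsort(two["final_fixation_ms"].to_numpy(), kind="stable")
    fix = two["final_fixation_ms"].to_numpy()[order]
    rt = two["rt_ms"].to_numpy()[order]
    candidates = np.unique(fix)
    best_cost, best_c = np.inf, float(candidates[0])
    for c in candidates:
        k = int(np.searchsorted(fix, c))  # trials with fixation < c
        cost = float(np.abs(rt[:k] - m1).sum())
        if k < len(rt):
            cost += float(np.abs(rt[k:] - np.median(rt[k:])).sum())
        if cost < best_cost - 1e-9:
            best_cost, best_c = cost, float(c)
    return best_c


def screen_stimulus_sets(
    pilot_trials: pd.DataFrame,
    rt_band: float = 0.6,
    min_accuracy: float = 0.75,
) -> list:
    """Select stimulus sets from pilot data.

    Reaction times are normalized per subject (mean 0, SD 1) and pooled per
    stimulus display across subjects.  A set is removed when any of its
    displays has an average normalized RT outside ``rt_band`` around the
    overall mean, or accuracy below ``min_accuracy``.
    """
    _require(pilot_trials, "stimulus_id", "rt_ms", "correct", "subject_id")
    df = pilot_trials.copy()
    z = np.empty(len(df))
    for s, grp in df.groupby("subject_id"):
        sd = grp["rt_ms"].std(ddof=0)
        if not sd > 0:
            raise ValueError(f"subject {s!r} has zero reaction-time variance")
        z[df["subject_id"] == s] = (grp["rt_ms"] - grp["rt_ms"].mean()) / sd
    df["rt_z"] = z
    grand_mean = df["rt_z"].mean()

    display_cols = ["stimulus_id"]
    if "postsac_stimulus" in df.columns:
        display_cols.append("postsac_stimulus")
    per_display = df.groupby(display_cols).agg(
        mean_z=("rt_z", "mean"), accuracy=("correct", "mean")
    )
    bad = per_display.loc[
        (np.abs(per_display["mean_z"] - grand_mean) > rt_band)
        | (per_display["accuracy"] < min_accuracy)
    ]
    bad_sets = (
        set(bad.index.get_level_values("stimulus_id"))
        if len(bad)
        else set()
    )
    return sorted(set(df["stimulus_id"]) - bad_sets)
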