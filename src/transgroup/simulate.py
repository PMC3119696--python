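"""Synthetic trial-level behavioral and eye-movement data.

The generator emulates the statistical structure the analysis pipeline
assumes for a five-condition transsaccadic grouping experiment:

* saccadic latencies from a shifted lognormal with per-condition location
  shifts (parameters solved so the default grand median and 10/90%
  percentiles are 213/182/287 ms);
* 2D saccade landing positions from condition-dependent isotropic normals
  (neutral Uniform/Random previews land less accurately than object-like
  Localized/Same/Different previews);
* manual reaction times that are lognormal ("log-normal noise, so a log
  transform is exactly variance-stabilizing") plus an additive condition
  effect, a linear dependence on landing error, and a penalty on trials
  whose final fixation before the response was slow;
* counts of additional target-directed saccades and fixation durations;
* near-ceiling response accuracy with a per-condition log-odds offset.

All quantities are configuration, not empirical claims; the defaults are
plausible-looking values consistent with the printed aggregate statistics
of the emulated study design.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from ._rng import as_rng

CONDITIONS = ("uniform", "random", "localized", "same", "different")

#: Mandatory trial-table columns.
TRIAL_COLUMNS = [
    "subject_id",
    "trial_id",
    "condition",
    "stimulus_id",
    "postsac_stimulus",
    "target_class",
    "saccade_latency_ms",
    "saccade_duration_ms",
    "landing_x_deg",
    "landing_y_deg",
    "n_additional_saccades",
    "final_fixation_ms",
    "initial_postsac_fixation_ms",
    "rt_ms",
    "response",
    "correct",
]


class TrialSchemaError(ValueError):
    """A trial table is missing a mandatory column."""


def _cond_map(value) -> dict[str, float]:
    if isinstance(value, Mapping):
        return {c: float(value[c]) for c in CONDITIONS}
    return {c: float(value) for c in CONDITIONS}


@dataclass
class SimulationConfig:
    """Full parameterization of one simulated experiment."""

    n_subjects: int = 7
    trials_per_condition: int = 100

    # saccadic latency: onset + condition shift + lognormal(mu, sigma),
    # with mu set so the grand median is latency_median_ms
    latency_median_ms: float = 213.0
    latency_onset_ms: float = 159.65
    latency_sigma_log: float = 0.679
    latency_shift_ms: dict = field(
        default_factory=lambda: {
            "uniform": 3.5, "random": 3.5, "localized": -3.5, "same": -3.5, "different": -3.5,
        }
    )
    latency_window_ms: tuple = (150.0, 500.0)

    # saccade landing: isotropic 2D normal per condition
    landing_bias_deg: dict = field(
        default_factory=lambda: {
            "uniform": (0.25, 0.0), "random": (0.25, 0.0),
            "localized": (0.08, 0.0), "same": (0.08, 0.0), "different": (0.08, 0.0),
        }
    )
    landing_sd_deg: dict = field(
        default_factory=lambda: {
            "uniform": 0.5, "random": 0.5, "localized": 0.28, "same": 0.28, "different": 0.28,
        }
    )

    # saccade duration: shift + lognormal
    duration_shift_ms: float = 45.0
    duration_mu_log: float = float(np.log(10.0))
    duration_sigma_log: float = 0.5

    # manual RT: exp(N(mu, sigma)) + condition effect + slope * ||landing||
    rt_mu_log: float = float(np.log(570.0))
    rt_sigma_log: float = 0.25
    condition_effect_ms: dict = field(
        default_factory=lambda: {
            "uniform": 0.0, "random": 0.0, "localized": -10.0, "same": -26.0, "different": 9.0,
        }
    )
    landing_slope_ms_per_deg: float = 40.0

    # additional saccades toward the target (3 encodes "3 or more") and the
    # final fixation duration before the manual response
    p_extra_saccades: dict = field(
        default_factory=lambda: {1: 0.80, 2: 0.173, 3: 0.027}
    )
    fixation_shift_ms: float = 150.0
    fixation_mu_log: float = float(np.log(111.0))
    fixation_sigma_log: float = 0.45
    #: trials with two extra saccades and a final fixation at or above this
    #: cutoff did not anticipate the response and are slower by the penalty
    slow_fixation_cutoff_ms: float = 240.0
    slow_fixation_penalty_ms: float = 190.0
    many_saccade_penalty_ms: float = 260.0

    initial_fixation_mean_ms: float = 210.0
    initial_fixation_sd_ms: float = 40.0

    # accuracy: logit = intercept + subject intercept + condition offset
    accuracy_logit: dict = field(
        default_factory=lambda: {
            "intercept": 3.0,
            "uniform": 0.0, "random": 0.0, "localized": 0.0, "same": 1.4, "different": 0.0,
        }
    )
    accuracy_subject_sd: float = 0.3

    n_stimulus_sets: int = 80
    intrafixation: bool = False
    seed: int | None = None

    def validate(self) -> None:
        p = np.array([self.p_extra_saccades[k] for k in (1, 2, 3)], dtype=float)
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("p_extra_saccades must be a probability vector over {1,2,3}")
        for c in CONDITIONS:
            if self.landing_sd_deg[c] <= 0:
                raise ValueError("landing spreads must be positive")
        if set(self.latency_shift_ms) != set(CONDITIONS):
            raise ValueError(f"latency_shift_ms must cover conditions {CONDITIONS}")

    # -- null / serialization ------------------------------------------------
    @classmethod
    def null(cls, **overrides) -> "SimulationConfig":
        """A configuration with no condition effects anywhere (exchangeable)."""
        cfg = cls(**overrides)
        cfg.latency_shift_ms = {c: 0.0 for c in CONDITIONS}
        cfg.landing_bias_deg = {c: (0.1, 0.0) for c in CONDITIONS}
        cfg.landing_sd_deg = {c: 0.35 for c in CONDITIONS}
        cfg.condition_effect_ms = {c: 0.0 for c in CONDITIONS}
        cfg.accuracy_logit = {"intercept": 3.0, **{c: 0.0 for c in CONDITIONS}}
        return cfg

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["latency_window_ms"] = list(self.latency_window_ms)
        d["landing_bias_deg"] = {c: list(v) for c, v in self.landing_bias_deg.items()}
        Path(path).write_text(yaml.safe_dump(d))

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["latency_window_ms"] = tuple(d["latency_window_ms"])
        d["landing_bias_deg"] = {c: tuple(v) for c, v in d["landing_bias_deg"].items()}
        d["p_extra_saccades"] = {int(k): v for k, v in d["p_extra_saccades"].items()}
        return cls(**d)


def _truncated_shifted_lognormal(rng, n, shift, mu, sigma, window):
    """Shifted lognormal draws resampled into the acquisition window."""
    shift = np.broadcast_to(np.asarray(shift, dtype=float), (n,))
    out = shift + np.exp(rng.normal(mu, sigma, n))
    for _ in range(100):
        bad = (out < window[0]) | (out > window[1])
        if not bad.any():
            break
        out[bad] = shift[bad] + np.exp(rng.normal(mu, sigma, int(bad.sum())))
    return np.clip(out, window[0], window[1])


def simulate_experiment(config: SimulationConfig, seed=None) -> pd.DataFrame:
    """Simulate a full experiment; fully reproducible under a fixed seed."""
    config.validate()
    rng = as_rng(config.seed if seed is None else seed)
    n_sub, n_cond = config.n_subjects, len(CONDITIONS)
    n_per = config.trials_per_condition
    n_trials = n_sub * n_cond * n_per

    subject = np.repeat(np.arange(n_sub), n_cond * n_per)
    cond = np.empty(n_trials, dtype=object)
    for s in range(n_sub):
        block = np.repeat(np.array(CONDITIONS, dtype=object), n_per)
        rng.shuffle(block)
        cond[s * n_cond * n_per : (s + 1) * n_cond * n_per] = block

    def per_cond(mapping) -> np.ndarray:
        m = {c: mapping[c] for c in CONDITIONS}
        return np.array([m[c] for c in cond])

    # latency
    mu_lat = np.log(config.latency_median_ms - config.latency_onset_ms)
    shift = config.latency_onset_ms + per_cond(config.latency_shift_ms)
    latency = _truncated_shifted_lognormal(
        rng, n_trials, shift, mu_lat, config.latency_sigma_log, config.latency_window_ms
    )

    # landing
    bias = np.array([config.landing_bias_deg[c] for c in cond], dtype=float)
    sd = per_cond(config.landing_sd_deg)[:, None]
    landing = bias + sd * rng.standard_normal((n_trials, 2))
    if config.intrafixation:
        landing = np.zeros_like(landing)
    landing_err = np.linalg.norm(landing, axis=1)

    duration = config.duration_shift_ms + np.exp(
        rng.normal(config.duration_mu_log, config.duration_sigma_log, n_trials)
    )

    extras = rng.choice(
        [1, 2, 3], size=n_trials, p=[config.p_extra_saccades[k] for k in (1, 2, 3)]
    )
    fixation = config.fixation_shift_ms + np.exp(
        rng.normal(config.fixation_mu_log, config.fixation_sigma_log, n_trials)
    )
    initial_fix = np.clip(
        rng.normal(config.initial_fixation_mean_ms, config.initial_fixation_sd_ms, n_trials),
        50.0,
        None,
    )

    # manual RT
    rt = np.exp(rng.normal(config.rt_mu_log, config.rt_sigma_log, n_trials))
    if not config.intrafixation:
        rt = rt + per_cond(config.condition_effect_ms)
        rt = rt + config.landing_slope_ms_per_deg * landing_err
    slow = (extras == 2) & (fixation >= config.slow_fixation_cutoff_ms)
    rt = rt + np.where(slow, config.slow_fixation_penalty_ms, 0.0)
    rt = rt + np.where(extras >= 3, config.many_saccade_penalty_ms, 0.0)

    # accuracy and response coding
    subj_int = rng.normal(0.0, config.accuracy_subject_sd, n_sub)
    logit = config.accuracy_logit["intercept"] + subj_int[subject] + per_cond(
        {c: config.accuracy_logit[c] for c in CONDITIONS}
    )
    correct = rng.random(n_trials) < 1.0 / (1.0 + np.exp(-logit))

    target_class = rng.choice(
        ["inside_both", "outside_both", "mixed"], size=n_trials, p=[0.25, 0.25, 0.5]
    )
    target_side = np.where(
        target_class == "inside_both",
        "in",
        np.where(
            target_class == "outside_both",
            "out",
            np.where(rng.random(n_trials) < 0.5, "in", "out"),
        ),
    )
    response = np.where(correct, target_side, np.where(target_side == "in", "out", "in"))

    return pd.DataFrame(
        {
            "subject_id": subject,
            "trial_id": np.arange(n_trials),
            "condition": cond,
            "stimulus_id": rng.integers(0, config.n_stimulus_sets, n_trials),
            "postsac_stimulus": rng.integers(1, 3, n_trials),
            "target_class": target_class,
            "saccade_latency_ms": latency,
            "saccade_duration_ms": duration,
            "landing_x_deg": landing[:, 0],
            "landing_y_deg": landing[:, 1],
            "n_additional_saccades": extras,
            "final_fixation_ms": fixation,
            "initial_postsac_fixation_ms": initial_fix,
            "rt_ms": rt,
            "response": response,
            "correct": correct,
            "target_side": target_side,
        }
    )


def write_trials(trials: pd.DataFrame, path) -> None:
    """Write a trial table to CSV (mandatory schema enforced)."""
    _check_schema(trials)
    trials.to_csv(Path(path), index=False)


def read_trials(path) -> pd.DataFrame:
    """Read a trial table from CSV; unknown columns are preserved."""
    df = pd.read_csv(Path(path))
    _check_schema(df)
    return df


def _check_schema(df: pd.DataFrame) -> None:
    for col in TRIAL_COLUMNS:
        if col not in df.columns:
            raise TrialSchemaError(f"trial table is missing mandatory column {col!r}")


def validate_response_coding(df: pd.DataFrame) -> np.ndarray:
    """Indices of trials whose correct flag contradicts response vs target side.

    For unambiguous target classes the true side follows from the class;
    for mixed displays the ``target_side`` column (if present) is used.
    """
    truth = np.where(
        df["target_class"] == "inside_both",
        "in",
        np.where(df["target_class"] == "outside_both", "out", ""),
    )
    if "target_side" in df.columns:
        truth = np.where(truth == "", df["target_side"].to_numpy(), truth)
    known = truth != ""
    consistent = (df["response"].to_numpy() == truth) == df["correct"].to_numpy()
    return np.flatnonzero(known & ~consistent)
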