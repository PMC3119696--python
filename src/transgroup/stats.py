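"""Descriptive and inferential analyses for grouping-experiment trial tables.

Implements the analysis battery of the experimental design: discrete-time
survival and hazard tables of latencies and reaction times, per-subject
median normalization for pooling, landing-error adjustment of log reaction
times, repeated-measures condition contrasts, an analysis of variance of
variance (AVOV) for landing spread, a within-subject logistic accuracy
model, highest-density iso-frequency regions of saccade landings, and the
coarse-shape (bounding box) analysis.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

from .contours import BoundingBox, axial_difference
from .render import CONDITIONS

#: Survival-table bin widths used in the study design, ms.
LATENCY_BIN_MS = 5.0
RT_BIN_MS = 15.0


# ---------------------------------------------------------------------------
# pooling and survival tables
# ---------------------------------------------------------------------------

def normalize_medians(values, subjects) -> np.ndarray:
    """Shift each subject's values so their median equals the overall median.

    Within-subject differences are exactly preserved (pure shift); after
    normalization every subject's median equals the median of the pooled
    raw values, so data can be pooled without between-subject location
    differences smearing the distribution shape.
    """
    values = np.asarray(values, dtype=float)
    subjects = np.asarray(subjects)
    if len(values) == 0:
        raise ValueError("no values to normalize")
    overall = np.median(values)
    out = np.empty_like(values)
    for s in np.unique(subjects):
        mask = subjects == s
        if not mask.any():
            raise ValueError(f"subject {s!r} has no values")
        out[mask] = values[mask] + (overall - np.median(values[mask]))
    return out


@dataclass
class SurvivalTable:
    """Binned survival, hazard, and smoothed hazard per condition."""

    bin_edges: np.ndarray  # length n_bins + 1, starting at 0
    survival: dict = field(default_factory=dict)  # condition -> array
    hazard: dict = field(default_factory=dict)
    smoothed_hazard: dict = field(default_factory=dict)

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cond in self.survival:
            rows.append(
                pd.DataFrame(
                    {
                        "condition": cond,
                        "bin_start": self.bin_edges[:-1],
                        "bin_end": self.bin_edges[1:],
                        "survival": self.survival[cond],
                        "hazard": self.hazard[cond],
                        "smoothed_hazard": self.smoothed_hazard[cond],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def moving_average(x: np.ndarray, window: int = 5) -> np.ndarray:
    """Centered moving average; the window shrinks symmetrically at the edges."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    half = window // 2
    out = np.empty(n)
    for i in range(n):
        h = min(half, i, n - 1 - i)
        out[i] = x[i - h : i + h + 1].mean()
    return out


def survival_hazard(
    values,
    bin_ms: float,
    smooth_bins: int = 5,
    conditions=None,
) -> SurvivalTable:
    """Discrete-time survival analysis of positive event times.

    Survival in bin k is the fraction of events later than the bin's upper
    edge; hazard is the conditional probability of the event inside the bin
    given survival to its start; the smoothed hazard applies a centered
    ``smooth_bins`` moving average.  With ``conditions`` given, one curve
    set per condition shares a common bin grid.
    """
    values = np.asarray(values, dtype=float)
    if len(values) == 0:
        raise ValueError("no event times")
    if not bin_ms > 0:
        raise ValueError("bin width must be positive")
    if np.any(values <= 0):
        raise ValueError("event times must be positive")
    n_bins = int(np.ceil(values.max() / bin_ms))
    edges = bin_ms * np.arange(n_bins + 1)
    table = SurvivalTable(bin_edges=edges)
    groups = (
        {"all": np.ones(len(values), dtype=bool)}
        if conditions is None
        else {c: np.asarray(conditions) == c for c in pd.unique(np.asarray(conditions))}
    )
    for cond, mask in groups.items():
        v = values[mask]
        # bin index with right-inclusive bins (0, b], (b, 2b], ...
        idx = np.clip(np.ceil(v / bin_ms).astype(int) - 1, 0, n_bins - 1)
        events = np.bincount(idx, minlength=n_bins).astype(float)
        n = float(len(v))
        cum = np.cumsum(events)
        survival = 1.0 - cum / n
        at_risk = np.concatenate([[n], n - cum[:-1]])
        with np.errstate(invalid="ignore", divide="ignore"):
            hazard = np.where(at_risk > 0, events / at_risk, 0.0)
        table.survival[cond] = survival
        table.hazard[cond] = hazard
        table.smoothed_hazard[cond] = moving_average(hazard, smooth_bins)
    return table


# ---------------------------------------------------------------------------
# reaction-time analysis
# ---------------------------------------------------------------------------

def adjust_rt_for_landing(trials: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Regress log RT onto landing error and project to a central landing.

    A single slope is fit at trial level with subject intercepts (no
    heterogeneity of slopes between conditions is assumed); the adjusted
    log RT is the observed log RT minus slope * landing distance, i.e. the
    predicted value at zero landing error plus the residual.  Returns the
    trial table with ``log_rt`` and ``log_rt_adj`` columns, and the slope
    (log-ms units per degree).
    """
    from .trials import landing_distance

    df = trials.copy()
    dist = landing_distance(df)
    if np.var(dist) == 0:
        raise ValueError("landing distances have zero variance; nothing to adjust")
    df["log_rt"] = np.log(df["rt_ms"].to_numpy())
    X = pd.get_dummies(df["subject_id"], drop_first=False, dtype=float)
    X.insert(0, "distance", dist)
    fit = sm.OLS(df["log_rt"].to_numpy(), X.to_numpy()).fit()
    slope = float(fit.params[0])
    df["log_rt_adj"] = df["log_rt"] - slope * dist
    return df, slope


@dataclass
class Contrast:
    """One planned contrast on condition cell means."""

    name: str
    estimate_log: float
    se: float
    F: float
    df: tuple[int, int]
    p: float
    diff_ms: float
    ci95_log: tuple[float, float]
    ci95_ms: tuple[float, float]


@dataclass
class EffectTable:
    """Repeated-measures condition analysis of adjusted log reaction times."""

    condition_means: dict
    omnibus_F: float
    omnibus_df: tuple[int, int]
    omnibus_p: float
    contrasts: list
    covariate_slope: float | None = None

    def contrasts_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "contrast": [c.name for c in self.contrasts],
                "estimate_log": [c.estimate_log for c in self.contrasts],
                "se": [c.se for c in self.contrasts],
                "F": [c.F for c in self.contrasts],
                "df1": [c.df[0] for c in self.contrasts],
                "df2": [c.df[1] for c in self.contrasts],
                "p": [c.p for c in self.contrasts],
                "diff_ms": [c.diff_ms for c in self.contrasts],
            }
        )


#: Planned contrasts: weights per condition, positive side minus negative side.
PLANNED_CONTRASTS = {
    "neutral_vs_object": {
        "uniform": 0.5, "random": 0.5, "localized": -1 / 3, "same": -1 / 3, "different": -1 / 3,
    },
    "uniform_vs_random": {"uniform": 1.0, "random": -1.0},
    "same_vs_different": {"same": 1.0, "different": -1.0},
    "same_vs_localized": {"same": 1.0, "localized": -1.0},
    "different_vs_localized": {"different": 1.0, "localized": -1.0},
}


def condition_contrasts(
    trials: pd.DataFrame,
    value_col: str = "log_rt_adj",
    conditions=CONDITIONS,
    planned: dict | None = None,
    covariate_slope: float | None = None,
) -> EffectTable:
    """Repeated-measures analysis of subject-by-condition cell means.

    Cell means of ``value_col`` are computed per subject and condition; the
    error term is the subject-by-condition interaction with
    ``(C - 1) * (S - 1)`` degrees of freedom, and each planned contrast is
    tested as F(1, dfe).  Millisecond differences are back-transformed from
    the log scale as the difference of the exponentiated group means.
    """
    planned = PLANNED_CONTRASTS if planned is None else planned
    subjects = np.sort(pd.unique(trials["subject_id"]))
    S, C = len(subjects), len(conditions)
    if S < 2:
        raise ValueError("need at least two subjects")
    cells = np.empty((S, C))
    for i, s in enumerate(subjects):
        for j, c in enumerate(conditions):
            vals = trials.loc[
                (trials["subject_id"] == s) & (trials["condition"] == c), value_col
            ]
            if len(vals) == 0:
                raise ValueError(f"missing cell: subject {s!r}, condition {c!r}")
            cells[i, j] = vals.mean()

    subj_mean = cells.mean(axis=1, keepdims=True)
    cond_mean = cells.mean(axis=0, keepdims=True)
    grand = cells.mean()
    resid = cells - subj_mean - cond_mean + grand
    dfe = (C - 1) * (S - 1)
    ms_error = float((resid**2).sum() / dfe)
    ms_cond = float(S * ((cond_mean - grand) ** 2).sum() / (C - 1))
    omnibus_F = ms_cond / ms_error if ms_error > 0 else 0.0
    omnibus_p = float(sps.f.sf(omnibus_F, C - 1, dfe)) if ms_error > 0 else 1.0

    cond_means = {c: float(cond_mean[0, j]) for j, c in enumerate(conditions)}
    tcrit = sps.t.ppf(0.975, dfe)
    out = []
    for name, weights in planned.items():
        w = np.array([weights.get(c, 0.0) for c in conditions])
        est = float(w @ cond_mean[0])
        se = float(np.sqrt(ms_error * (w**2).sum() / S))
        F = (est / se) ** 2 if se > 0 else 0.0
        p = float(sps.f.sf(F, 1, dfe)) if se > 0 else 1.0
        pos, neg = w > 0, w < 0
        mean_pos = float((w[pos] @ cond_mean[0, pos]) / w[pos].sum()) if pos.any() else grand
        mean_neg = float((w[neg] @ cond_mean[0, neg]) / w[neg].sum()) if neg.any() else grand
        diff_ms = float(np.exp(mean_pos) - np.exp(mean_neg))
        lo, hi = est - tcrit * se, est + tcrit * se
        scale = float(np.exp(0.5 * (mean_pos + mean_neg)))
        out.append(
            Contrast(
                name=name,
                estimate_log=est,
                se=se,
                F=float(F),
                df=(1, dfe),
                p=p,
                diff_ms=diff_ms,
                ci95_log=(float(lo), float(hi)),
                ci95_ms=(float(lo * scale), float(hi * scale)),
            )
        )
    return EffectTable(
        condition_means=cond_means,
        omnibus_F=float(omnibus_F),
        omnibus_df=(C - 1, dfe),
        omnibus_p=omnibus_p,
        contrasts=out,
        covariate_slope=covariate_slope,
    )


# ---------------------------------------------------------------------------
# landing-position analyses
# ---------------------------------------------------------------------------

@dataclass
class AvovResult:
    """Analysis of variance of variance (dispersion comparison)."""

    F: float
    df: tuple[int, int]
    p: float
    contrast_F: float | None = None
    contrast_p: float | None = None
    group_mean_sqdev: dict = field(default_factory=dict)


def avov_spread(
    landings: np.ndarray,
    groups,
    contrast: tuple | None = None,
) -> AvovResult:
    """Compare landing-position spread between groups.

    Each trial contributes its squared Euclidean deviation from its group's
    mean landing point; a one-way ANOVA on these squared deviations tests
    dispersion differences, and an optional two-group-set contrast
    ``(set_a, set_b)`` tests a planned comparison of dispersion.
    """
    landings = np.asarray(landings, dtype=float).reshape(-1, 2)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    sqdev = np.empty(len(landings))
    for g in labels:
        mask = groups == g
        if mask.sum() < 2:
            raise ValueError(f"group {g!r} has fewer than two trials")
        sqdev[mask] = ((landings[mask] - landings[mask].mean(axis=0)) ** 2).sum(axis=1)

    k, n = len(labels), len(sqdev)
    grand = sqdev.mean()
    means = {g: float(sqdev[groups == g].mean()) for g in labels}
    counts = {g: int((groups == g).sum()) for g in labels}
    ss_between = sum(counts[g] * (means[g] - grand) ** 2 for g in labels)
    ss_within = sum(((sqdev[groups == g] - means[g]) ** 2).sum() for g in labels)
    df1, df2 = k - 1, n - k
    F = (ss_between / df1) / (ss_within / df2)
    result = AvovResult(
        F=float(F), df=(df1, df2), p=float(sps.f.sf(F, df1, df2)), group_mean_sqdev=means
    )
    if contrast is not None:
        set_a, set_b = contrast
        w = {g: (1 / len(set_a) if g in set_a else (-1 / len(set_b) if g in set_b else 0.0)) for g in labels}
        est = sum(w[g] * means[g] for g in labels)
        mse = ss_within / df2
        se = np.sqrt(mse * sum(w[g] ** 2 / counts[g] for g in labels))
        Fc = (est / se) ** 2 if se > 0 else 0.0
        result.contrast_F = float(Fc)
        result.contrast_p = float(sps.f.sf(Fc, 1, df2))
    return result


@dataclass
class IsoFrequencyRegion:
    """Highest-density 2D histogram region enclosing a target mass."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    mask: np.ndarray  # boolean (nx, ny) selected-bin mask
    enclosed_mass: float
    median_point: tuple[float, float]

    @property
    def area(self) -> float:
        bin_area = float(np.diff(self.x_edges)[0] * np.diff(self.y_edges)[0])
        return float(self.mask.sum()) * bin_area


def landing_isofrequency(
    landings: np.ndarray,
    bin_px: int = 10,
    ppd: float = 800.0 / 17.0,
    mass: float = 0.90,
    halfwidth: float = 1.9,
) -> IsoFrequencyRegion:
    """Iso-frequency (highest-density) region of saccade landing positions.

    Landings are histogrammed over the display with ``bin_px``-pixel bins;
    bins are added in decreasing-count order until the enclosed mass first
    reaches ``mass``.  The marker point combines the marginal medians of
    the landing coordinates.
    """
    if not (0.0 < mass < 1.0):
        raise ValueError("mass must be in (0, 1)")
    landings = np.asarray(landings, dtype=float).reshape(-1, 2)
    if len(landings) < 10:
        raise ValueError("need at least 10 landing positions")
    bin_deg = bin_px / ppd
    n_bins = int(np.ceil(2 * halfwidth / bin_deg))
    edges = -halfwidth + bin_deg * np.arange(n_bins + 1)
    counts, xe, ye = np.histogram2d(landings[:, 0], landings[:, 1], bins=(edges, edges))
    order = np.argsort(counts.ravel())[::-1]
    cum = np.cumsum(counts.ravel()[order])
    total = counts.sum()
    need = int(np.searchsorted(cum, mass * total) + 1)
    mask = np.zeros(counts.size, dtype=bool)
    mask[order[:need]] = True
    return IsoFrequencyRegion(
        x_edges=xe,
        y_edges=ye,
        mask=mask.reshape(counts.shape),
        enclosed_mass=float(cum[need - 1] / total),
        median_point=(float(np.median(landings[:, 0])), float(np.median(landings[:, 1]))),
    )


# ---------------------------------------------------------------------------
# accuracy
# ---------------------------------------------------------------------------

def accuracy_logistic(
    trials: pd.DataFrame, baseline: str = "uniform"
) -> pd.DataFrame:
    """Within-subject logistic regression of correctness on condition.

    Fits correct ~ condition + subject (fixed subject intercepts) by
    maximum likelihood and returns per-condition log-odds versus the
    ``baseline`` condition with Wald statistics.
    """
    conds = [c for c in CONDITIONS if c != baseline]
    X = pd.DataFrame({"const": np.ones(len(trials))})
    for c in conds:
        X[f"cond[{c}]"] = (trials["condition"] == c).astype(float)
    subjects = np.sort(pd.unique(trials["subject_id"]))
    for s in subjects[1:]:
        X[f"subj[{s}]"] = (trials["subject_id"] == s).astype(float)
    y = trials["correct"].astype(float).to_numpy()
    if y.min() == y.max():
        raise ValueError(
            "complete separation (all responses identical); consider a penalized fit"
        )
    model = sm.GLM(y, X.to_numpy(), family=sm.families.Binomial())
    fit = model.fit()
    names = list(X.columns)
    rows = []
    for c in conds:
        j = names.index(f"cond[{c}]")
        beta, se = float(fit.params[j]), float(fit.bse[j])
        rows.append(
            {
                "condition": c,
                "beta": beta,
                "se": se,
                "z": beta / se if se > 0 else np.nan,
                "p": float(2 * sps.norm.sf(abs(beta / se))) if se > 0 else np.nan,
                "ci95_lo": beta - 1.959963984540054 * se,
                "ci95_hi": beta + 1.959963984540054 * se,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# coarse shape properties
# ---------------------------------------------------------------------------

@dataclass
class CoarseShapeResult:
    """Bounding-box (aspect ratio / orientation) analysis of Different trials."""

    n_different: int
    n_elongated: int
    elongated_fraction: float
    r_orientation: float | None  # mean within-subject correlation, elongated subset
    t_orientation: float | None
    p_orientation: float | None
    cost_full_ms: float | None  # Different - Localized cost, all trials
    cost_excluding_ms: float | None  # after excluding large orientation differences
    cost_reduction: float | None
    r_aspect: float | None  # complement subset, RT vs relative aspect ratio
    t_aspect: float | None
    p_aspect: float | None


def _within_subject_correlation(df: pd.DataFrame, xcol: str, ycol: str):
    """Mean per-subject Pearson correlation with a t test across subjects."""
    rs = []
    for _, grp in df.groupby("subject_id"):
        if len(grp) >= 3 and grp[xcol].std() > 0 and grp[ycol].std() > 0:
            rs.append(sps.pearsonr(grp[xcol], grp[ycol]).statistic)
    if len(rs) < 2:
        return None, None, None
    rs = np.asarray(rs)
    t = rs.mean() / (rs.std(ddof=1) / np.sqrt(len(rs)))
    return float(rs.mean()), float(t), float(2 * sps.t.sf(abs(t), len(rs) - 1))


def coarse_shape_analysis(
    trials: pd.DataFrame,
    boxes: dict,
    ar_threshold: float = 1.2,
    ori_threshold: float = 33.0,
    value_col: str = "log_rt_adj",
) -> CoarseShapeResult:
    """Relate Different-preview costs to coarse shape (mis)match.

    ``boxes`` maps stimulus_id to the pair of minimum bounding rectangles
    of the two latent contours.  Elongated trials (both aspect ratios above
    ``ar_threshold``) are tested for a within-subject correlation between
    the adjusted log RT and the axial orientation difference of the two
    shapes; the Different-versus-Localized cost is recomputed after
    excluding elongated pairs with orientation differences above
    ``ori_threshold``; and on the complementary subset the adjusted log RT
    is correlated with the relative aspect ratio of preview and test shape.
    """
    df = trials.copy()

    def pair(sid):
        b1, b2 = boxes[sid]
        return b1, b2

    ori_diff = np.empty(len(df))
    ar_pre = np.empty(len(df))
    ar_post = np.empty(len(df))
    for i, (_, row) in enumerate(df.iterrows()):
        b1, b2 = pair(row["stimulus_id"])
        post = b1 if row["postsac_stimulus"] == 1 else b2
        pre = b2 if row["postsac_stimulus"] == 1 else b1
        ori_diff[i] = axial_difference(pre.orientation, post.orientation)
        ar_pre[i], ar_post[i] = pre.aspect_ratio, post.aspect_ratio
    df["ori_diff"] = ori_diff
    df["ar_pre"] = ar_pre
    df["ar_post"] = ar_post
    df["rel_aspect"] = ar_pre / ar_post

    diff_trials = df[df["condition"] == "different"]
    elong = diff_trials[
        (diff_trials["ar_pre"] > ar_threshold) & (diff_trials["ar_post"] > ar_threshold)
    ]
    r_o, t_o, p_o = (
        _within_subject_correlation(elong, "ori_diff", value_col)
        if len(elong)
        else (None, None, None)
    )

    cost_full = cost_excl = reduction = None
    loc = df[df["condition"] == "localized"]
    if len(loc) and len(diff_trials):
        base = float(np.exp(loc[value_col].mean()))
        cost_full = float(np.exp(diff_trials[value_col].mean()) - base)
        keep = ~(
            (diff_trials["ar_pre"] > ar_threshold)
            & (diff_trials["ar_post"] > ar_threshold)
            & (diff_trials["ori_diff"] > ori_threshold)
        )
        if keep.any():
            cost_excl = float(np.exp(diff_trials.loc[keep, value_col].mean()) - base)
            reduction = (cost_full - cost_excl) / cost_full if cost_full else None

    complement = diff_trials[
        (diff_trials["ar_pre"] < ar_threshold)
        | (diff_trials["ar_post"] < ar_threshold)
        | (diff_trials["ori_diff"] <= ori_threshold)
    ]
    r_a, t_a, p_a = (
        _within_subject_correlation(complement, "rel_aspect", value_col)
        if len(complement)
        else (None, None, None)
    )

    return CoarseShapeResult(
        n_different=len(diff_trials),
        n_elongated=len(elong),
        elongated_fraction=len(elong) / len(diff_trials) if len(diff_trials) else 0.0,
        r_orientation=r_o,
        t_orientation=t_o,
        p_orientation=p_o,
        cost_full_ms=cost_full,
        cost_excluding_ms=cost_excl,
        cost_reduction=reduction,
        r_aspect=r_a,
        t_aspect=t_a,
        p_aspect=p_a,
    )
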