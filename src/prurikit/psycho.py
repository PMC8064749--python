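"""gLMS psychophysics: rating metrics, subject filters, and repeated-measures ANOVA.

Subjects rate itch, pricking/stinging and burning on the generalized
Labeled Magnitude Scale (gLMS, 0–100 with quasi-logarithmic verbal
anchors) every 30 s after an intradermal injection, for at least 5 and at
most 20 min or until every quality has received three successive zero
ratings.  Per series the analysis extracts the peak rating, the duration
of the sensation (first nonzero rating to the first zero after the
sensation disappeared; censored at session end), and the area under the
rating curve (trapezoidal, with an implicit zero half a minute before
onset).  Group comparisons use within-subject RM-ANOVA with the
Greenhouse–Geisser correction and Bonferroni post hoc tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Set, Union

import numpy as np
import pandas as pd

from .stats import TestResult, bonferroni_pairwise, mixed_anova, rm_anova_gg

__all__ = [
    "GLMS_ANCHORS",
    "RATING_STEP_MIN",
    "SESSION_MIN_MIN",
    "SESSION_MAX_MIN",
    "RatingSeries",
    "SensationMetrics",
    "SessionValidation",
    "validate_session",
    "peak_rating",
    "sensation_duration",
    "rating_auc",
    "sensation_metrics",
    "metrics_table",
    "filter_all_nonzero",
    "filter_balanced_itch",
    "rmanova_gg",
    "rmanova_with_sex_screen",
    "area_analysis",
]

#: gLMS verbal anchors and their numeric positions on the 0–100 scale.
GLMS_ANCHORS: Dict[str, float] = {
    "no sensation": 0.0,
    "barely detectable": 1.0,
    "weak": 6.0,
    "moderate": 17.0,
    "strong": 35.0,
    "very strong": 53.0,
    "strongest imaginable": 100.0,
}

RATING_STEP_MIN = 0.5
SESSION_MIN_MIN = 5.0
SESSION_MAX_MIN = 20.0


@dataclass(frozen=True)
class RatingSeries:
    """gLMS magnitudes of one subject × stimulus × sensory quality on the 0.5-min grid."""

    subject_id: str
    stimulus: str
    quality: str
    times_min: np.ndarray
    magnitudes: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times_min, dtype=float)
        m = np.asarray(self.magnitudes, dtype=float)
        if t.shape != m.shape or t.ndim != 1 or t.size == 0:
            raise ValueError("times and magnitudes must be equal-length non-empty 1-D")
        if np.any((m < 0) | (m > 100)):
            raise ValueError("gLMS magnitudes must lie in [0, 100]")
        object.__setattr__(self, "times_min", t)
        object.__setattr__(self, "magnitudes", m)

    @property
    def session_end_min(self) -> float:
        return float(self.times_min[-1])


@dataclass(frozen=True)
class SensationMetrics:
    """Peak, duration (possibly censored) and AUC of one rating series."""

    subject_id: str
    stimulus: str
    quality: str
    peak: float
    duration_min: Optional[float]
    censored: bool
    auc: Optional[float]


@dataclass(frozen=True)
class SessionValidation:
    subject_id: str
    stimulus: str
    valid: bool
    flags: tuple


def validate_session(series_set: Sequence[RatingSeries]) -> SessionValidation:
    """Check one subject × stimulus session against the rating protocol.

    Flags raised: ``grid_gap`` (missing 0.5-min sample or first sample not
    at 0.5 min), ``below_minimum`` (ended before 5 min), ``early_stop``
    (ended before 20 min although some quality had not yet produced three
    successive zeros), ``quality_grid_mismatch``.  Sessions still nonzero
    at the 20-min cap are valid (censored).
    """
    if not series_set:
        raise ValueError("empty session")
    sid = series_set[0].subject_id
    stim = series_set[0].stimulus
    flags: List[str] = []
    grids = {tuple(np.round(s.times_min, 6)) for s in series_set}
    if len(grids) > 1:
        flags.append("quality_grid_mismatch")
    ref = series_set[0].times_min
    expected = np.arange(1, ref.size + 1) * RATING_STEP_MIN
    if not np.allclose(ref, expected):
        flags.append("grid_gap")
    end = series_set[0].session_end_min
    if end < SESSION_MIN_MIN:
        flags.append("below_minimum")
    elif end < SESSION_MAX_MIN:
        # legal stop only once every quality shows 3 successive terminal zeros
        for s in series_set:
            if s.magnitudes.size < 3 or np.any(s.magnitudes[-3:] != 0):
                flags.append("early_stop")
                break
    return SessionValidation(sid, stim, valid=not flags, flags=tuple(flags))


def peak_rating(series: RatingSeries) -> float:
    """Highest rating of magnitude over the session."""
    return float(series.magnitudes.max())


def sensation_duration(series: RatingSeries) -> tuple:
    """Duration of the sensation in minutes, with a censoring flag.

    Measured from the first nonzero rating to the first zero rating after
    the *last* nonzero rating (intermediate zeros during a waxing/waning
    sensation do not terminate it).  If the session ends while the
    sensation is still present (20-min cap), the duration runs to the
    session end and is flagged censored.
    """
    m = series.magnitudes
    nz = np.flatnonzero(m > 0)
    if nz.size == 0:
        raise ValueError("no sensation: all ratings zero")
    t_on = float(series.times_min[nz[0]])
    last_nz = nz[-1]
    if last_nz == m.size - 1:
        return series.session_end_min - t_on, True
    t_off = float(series.times_min[last_nz + 1])
    return t_off - t_on, False


def rating_auc(series: RatingSeries) -> float:
    """Area under the rating curve (gLMS·min) for the duration of the sensation.

    Trapezoidal integration on the 0.5-min grid from an implicit zero at
    ``t_on − 0.5`` through the last sample of the sensation (the first
    zero after the last nonzero rating, or the session end if censored).
    """
    m = series.magnitudes
    nz = np.flatnonzero(m > 0)
    if nz.size == 0:
        raise ValueError("no sensation: all ratings zero")
    first, last = nz[0], nz[-1]
    stop = min(last + 1, m.size - 1)  # include the terminating zero when present
    t = series.times_min[first : stop + 1]
    y = m[first : stop + 1]
    t = np.concatenate([[t[0] - RATING_STEP_MIN], t])
    y = np.concatenate([[0.0], y])
    return float(np.trapezoid(y, t))


def sensation_metrics(series: RatingSeries) -> SensationMetrics:
    """Peak / duration / AUC bundle; duration and AUC undefined when peak is 0."""
    pk = peak_rating(series)
    if pk == 0:
        return SensationMetrics(
            series.subject_id, series.stimulus, series.quality, 0.0, None, False, None
        )
    dur, censored = sensation_duration(series)
    return SensationMetrics(
        series.subject_id,
        series.stimulus,
        series.quality,
        pk,
        dur,
        censored,
        rating_auc(series),
    )


def metrics_table(series_list: Sequence[RatingSeries]) -> pd.DataFrame:
    """Tidy per-series metrics: subject_id, stimulus, quality, peak, duration, censored, auc."""
    rows = [sensation_metrics(s).__dict__ for s in series_list]
    return pd.DataFrame(rows)


def filter_all_nonzero(
    metrics: pd.DataFrame,
    stimuli: Optional[Sequence[str]] = None,
    qualities: Optional[Sequence[str]] = None,
) -> Set[str]:
    """Subjects with a nonzero peak for every quality × stimulus combination.

    Subjects with incomplete data (missing combinations) are excluded with
    a warning.
    """
    stimuli = sorted(metrics["stimulus"].unique()) if stimuli is None else list(stimuli)
    qualities = (
        sorted(metrics["quality"].unique()) if qualities is None else list(qualities)
    )
    need = len(stimuli) * len(qualities)
    keep: Set[str] = set()
    for sid, grp in metrics.groupby("subject_id"):
        sub = grp[grp["stimulus"].isin(stimuli) & grp["quality"].isin(qualities)]
        if len(sub.drop_duplicates(["stimulus", "quality"])) < need:
            warnings.warn(f"subject {sid}: incomplete data, excluded", stacklevel=2)
            continue
        if (sub["peak"] > 0).all():
            keep.add(sid)
    return keep


def filter_balanced_itch(
    metrics: pd.DataFrame,
    pruritogens: Sequence[str] = ("ALA", "BAM", "HIS"),
    ratio: float = 0.5,
) -> Set[str]:
    """Subjects whose weakest single-pruritogen peak itch is ≥ ratio × their strongest."""
    itch = metrics[(metrics["quality"] == "itch") & metrics["stimulus"].isin(pruritogens)]
    keep: Set[str] = set()
    for sid, grp in itch.groupby("subject_id"):
        peaks = grp.set_index("stimulus")["peak"]
        if len(peaks) < len(pruritogens):
            continue
        if peaks.min() >= ratio * peaks.max():
            keep.add(sid)
    return keep


def rmanova_gg(
    data: pd.DataFrame,
    dv: str,
    within: Union[str, Sequence[str]],
    subject: str = "subject_id",
    posthoc: Optional[str] = None,
) -> List[TestResult]:
    """Within-subject RM-ANOVA with Greenhouse–Geisser correction.

    One or two within factors; subjects with missing cells are excluded
    listwise.  When ``posthoc`` names a within factor, Bonferroni-adjusted
    pairwise comparisons on its marginal means are appended to the result
    list.  See :func:`prurikit.stats.rm_anova_gg` for the estimator.
    """
    results = rm_anova_gg(data, dv=dv, within=within, subject=subject)
    if posthoc is not None:
        within_list = [within] if isinstance(within, str) else list(within)
        collapse = [w for w in within_list if w != posthoc]
        results.extend(
            bonferroni_pairwise(data, dv=dv, within=posthoc, subject=subject,
                                collapse=collapse or None)
        )
    return results


def rmanova_with_sex_screen(
    data: pd.DataFrame,
    dv: str,
    within: Sequence[str],
    subject: str = "subject_id",
    sex: str = "sex",
    alpha: float = 0.05,
) -> Dict[str, List[TestResult]]:
    """Screen the between-subjects sex factor, then run the within-design RM-ANOVA.

    Sex is screened with a mixed ANOVA on each within factor's marginal
    means (pingouin provides no three-way mixed model, and the study
    protocol drops sex at this step).  If no sex main effect or
    interaction reaches ``alpha`` the factor is excluded and the two-way
    within RM-ANOVA with GG correction is returned under ``"final"``;
    otherwise per-sex within models are returned instead.
    """
    screen: List[TestResult] = []
    for w in within:
        others = [x for x in within if x != w]
        marg = data.groupby([subject, sex, w], as_index=False)[dv].mean() if others else data
        screen.extend(mixed_anova(marg, dv=dv, within=w, between=sex, subject=subject))
    sex_terms = [r for r in screen if sex.lower() in r.effect.lower() or
                 r.effect == "Interaction"]
    sex_significant = any(r.p_value < alpha for r in sex_terms)
    out = {"sex_screen": screen}
    if sex_significant:
        per_sex: List[TestResult] = []
        for level, grp in data.groupby(sex):
            for r in rm_anova_gg(grp, dv=dv, within=list(within), subject=subject):
                per_sex.append(
                    TestResult(r.method, r.statistic, r.df, r.p_value,
                               effect=f"{r.effect} | {sex}={level}", details=r.details)
                )
        out["final"] = per_sex
    else:
        out["final"] = rm_anova_gg(data, dv=dv, within=list(within), subject=subject)
    return out


def area_analysis(
    areas: pd.DataFrame,
    measures: Optional[Sequence[str]] = None,
    subject: str = "subject_id",
) -> Dict[str, List[TestResult]]:
    """One RM-ANOVA (GG-corrected) per dysesthesia/skin measure across stimuli.

    ``areas`` is tidy with columns subject_id, stimulus, measure, area_cm2.
    Each measure (alloknesis, hyperalgesia, hyperknesis, wheal, flare) is
    analysed separately with Bonferroni pairwise post hoc across stimuli.
    """
    if np.any(areas["area_cm2"] < 0):
        raise ValueError("areas must be non-negative")
    measures = sorted(areas["measure"].unique()) if measures is None else list(measures)
    out: Dict[str, List[TestResult]] = {}
    for meas in measures:
        sub = areas[areas["measure"] == meas]
        res = rm_anova_gg(sub, dv="area_cm2", within="stimulus", subject=subject)
        res.extend(
            bonferroni_pairwise(sub, dv="area_cm2", within="stimulus", subject=subject)
        )
        out[meas] = res
    return out
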