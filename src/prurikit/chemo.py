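"""Scoring of pruritogen-evoked C-fiber responses and the associated statistics.

Each intradermal injection (β-alanine/ALA, BAM8-22, histamine, or a vehicle
control such as extracellular fluid or BAM8-18) is scored as a *net
response*: the action potentials recorded during the 5-min post-injection
window, minus the spontaneous baseline prorated from the 1-min
pre-injection recording, minus the same quantity for the vehicle.  A fiber
counts as responsive to a pruritogen when the net response is ≥10 APs per
5 min.  Population time courses use 10-s bins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .stats import TestResult, chi_square_2x2, mixed_anova, paired_t, scheffe_posthoc

__all__ = [
    "InjectionRecording",
    "NetResponse",
    "TimeCourse",
    "ContingencyTable2x2",
    "RESPONSIVE_THRESHOLD_APS",
    "prorated_baseline",
    "net_response",
    "bin_time_course",
    "joint_responsiveness_table",
    "association_chi_square",
    "paired_t",
    "mixed_anova_fiber_pruritogen",
    "scheffe_fiber_pruritogen",
]

BASELINE_WINDOW_S = 60.0
RESPONSIVE_THRESHOLD_APS = 10.0


@dataclass(frozen=True)
class InjectionRecording:
    """One intradermal injection for one fiber.

    ``post_spikes`` are AP timestamps in seconds relative to injection
    *start*; ``injection_interval`` is (start, end) in the same time base,
    so start is normally 0.  ``baseline_count`` is the number of APs in
    the 60-s pre-injection window.  Recordings terminated early (three
    silent consecutive minutes) are zero-padded to the analysis window.
    """

    fiber_id: str
    compound: str
    baseline_count: int
    injection_interval: Tuple[float, float]
    post_spikes: np.ndarray
    observation_s: float = 300.0

    def __post_init__(self) -> None:
        if self.baseline_count < 0:
            raise ValueError("baseline count must be non-negative")
        start, end = self.injection_interval
        if end < start:
            raise ValueError("injection interval end precedes start")
        ts = np.sort(np.asarray(self.post_spikes, dtype=float))
        object.__setattr__(self, "post_spikes", ts)

    @property
    def injection_duration_s(self) -> float:
        return self.injection_interval[1] - self.injection_interval[0]


@dataclass(frozen=True)
class NetResponse:
    """Baseline- and vehicle-corrected response of one fiber to one compound."""

    fiber_id: str
    compound: str
    total_aps: int
    prorated_baseline: float
    vehicle_net: float
    net_aps: float
    responsive: bool


@dataclass(frozen=True)
class TimeCourse:
    """Post-injection AP counts on a fixed-width bin grid."""

    fiber_id: str
    compound: str
    bin_edges: np.ndarray
    counts: np.ndarray


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Joint responsiveness counts: both / A-only / B-only / neither."""

    both: int
    a_only: int
    b_only: int
    neither: int

    def __post_init__(self) -> None:
        if min(self.both, self.a_only, self.b_only, self.neither) < 0:
            raise ValueError("cell counts must be non-negative")
        if self.n == 0:
            raise ValueError("empty table")

    @property
    def n(self) -> int:
        return self.both + self.a_only + self.b_only + self.neither


def prorated_baseline(baseline_count: int, window_s: float) -> float:
    """Expected spontaneous APs over ``window_s``, prorated from the 60-s baseline."""
    if baseline_count < 0:
        raise ValueError("baseline count must be non-negative")
    if window_s <= 0:
        raise ValueError("window must be positive")
    return baseline_count * window_s / BASELINE_WINDOW_S


def _windowed_count(
    rec: InjectionRecording, window_s: float, from_injection_end: bool
) -> int:
    start = rec.injection_duration_s if from_injection_end else 0.0
    ts = rec.post_spikes
    return int(np.count_nonzero((ts > start) & (ts <= start + window_s)))


def _single_net(
    rec: InjectionRecording, window_s: float, from_injection_end: bool
) -> Tuple[int, float, float]:
    total = _windowed_count(rec, window_s, from_injection_end)
    prorated = prorated_baseline(rec.baseline_count, window_s)
    return total, prorated, total - prorated


def net_response(
    pruritogen: InjectionRecording,
    vehicle: InjectionRecording,
    window_s: float = 300.0,
    from_injection_end: bool = True,
) -> NetResponse:
    """Net pruritogen response of one fiber, vehicle- and baseline-corrected.

    net = (APs in window − prorated baseline) for the pruritogen minus the
    same quantity for the vehicle.  The analysis window starts at the end
    of the injection interval by default (spikes during needle insertion
    and injection are excluded); pass ``from_injection_end=False`` to
    count from injection start.  Negative nets are retained; the
    responsiveness flag applies the ≥10 APs / 5 min rule to the signed
    value.
    """
    if pruritogen.fiber_id != vehicle.fiber_id:
        raise ValueError(
            f"fiber mismatch: {pruritogen.fiber_id!r} vs {vehicle.fiber_id!r}"
        )
    total, prorated, net_p = _single_net(pruritogen, window_s, from_injection_end)
    _, _, net_v = _single_net(vehicle, window_s, from_injection_end)
    net = net_p - net_v
    return NetResponse(
        fiber_id=pruritogen.fiber_id,
        compound=pruritogen.compound,
        total_aps=total,
        prorated_baseline=prorated,
        vehicle_net=net_v,
        net_aps=net,
        responsive=net >= RESPONSIVE_THRESHOLD_APS,
    )


def bin_time_course(
    rec: InjectionRecording,
    bin_s: float = 10.0,
    duration_s: float = 300.0,
    from_injection_end: bool = True,
) -> TimeCourse:
    """Post-injection AP counts in half-open bins [k·bin, (k+1)·bin).

    The grid covers ``duration_s`` from the start of the analysis window
    (injection end by default); ``bin_s`` must divide ``duration_s``.
    """
    if bin_s <= 0:
        raise ValueError("bin width must be positive")
    n_bins = duration_s / bin_s
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError("bin width must divide the duration")
    offset = rec.injection_duration_s if from_injection_end else 0.0
    edges = offset + np.arange(round(n_bins) + 1) * bin_s
    ts = rec.post_spikes
    # np.histogram's last bin is closed; enforce half-open throughout
    counts = np.array(
        [np.count_nonzero((ts >= lo) & (ts < hi)) for lo, hi in zip(edges[:-1], edges[1:])],
        dtype=int,
    )
    return TimeCourse(rec.fiber_id, rec.compound, edges - offset, counts)


def joint_responsiveness_table(
    responses_a: Sequence[NetResponse], responses_b: Sequence[NetResponse]
) -> ContingencyTable2x2:
    """Cross-tabulate per-fiber responsiveness to two compounds (Venn cells)."""
    flag_a = {r.fiber_id: r.responsive for r in responses_a}
    flag_b = {r.fiber_id: r.responsive for r in responses_b}
    common = sorted(set(flag_a) & set(flag_b))
    if not common:
        raise ValueError("no fibers tested with both compounds")
    both = sum(flag_a[f] and flag_b[f] for f in common)
    a_only = sum(flag_a[f] and not flag_b[f] for f in common)
    b_only = sum(flag_b[f] and not flag_a[f] for f in common)
    neither = len(common) - both - a_only - b_only
    return ContingencyTable2x2(both, a_only, b_only, neither)


def association_chi_square(table: ContingencyTable2x2) -> TestResult:
    """Pearson χ²(1) of association between responsiveness to two compounds.

    Computed without continuity correction on the joint table
    (both, A-only, B-only, neither); see :func:`prurikit.stats.chi_square_2x2`.
    """
    return chi_square_2x2(table.both, table.a_only, table.b_only, table.neither)


def mixed_anova_fiber_pruritogen(
    data: pd.DataFrame,
    dv: str = "net_aps",
    within: str = "compound",
    between: str = "fiber_type",
    subject: str = "fiber_id",
) -> List[TestResult]:
    """Split-plot ANOVA: fiber type (between) × pruritogen (within) on net responses.

    Fibers missing one within-condition are excluded listwise with a
    warning.  With the usual 2-level pruritogen factor the sphericity
    correction factor is 1.
    """
    counts = data.groupby(subject)[within].nunique()
    n_levels = data[within].nunique()
    dropped = counts[counts < n_levels]
    if len(dropped):
        warnings.warn(
            f"excluding {len(dropped)} fibers missing a within-condition: "
            f"{list(dropped.index)[:5]}...",
            stacklevel=2,
        )
    return mixed_anova(data, dv=dv, within=within, between=between, subject=subject)


def scheffe_fiber_pruritogen(
    data: pd.DataFrame,
    dv: str = "net_aps",
    within: str = "compound",
    between: str = "fiber_type",
    subject: str = "fiber_id",
    comparisons: Optional[Sequence] = None,
) -> List[TestResult]:
    """Scheffé post hoc contrasts among the fiber-type × pruritogen cell means."""
    return scheffe_posthoc(
        data, dv=dv, within=within, between=between, subject=subject,
        comparisons=comparisons,
    )
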