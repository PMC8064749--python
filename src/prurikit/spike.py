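"""Spike trains, heat stimuli, and QC/SC classification of CMH heat responses.

Polymodal mechanoheat-sensitive C-fibers (CMHs) fall into two subtypes by
their response to a stepped heat stimulus: quickly adapting fibers (QC)
fire a burst of discharge at the onset of the temperature ramp and then
adapt during the plateau, while slowly adapting fibers (SC) ramp up and
reach their peak instantaneous frequency during the plateau.  The formal
separation plots the time of peak (median-smoothed) instantaneous
discharge frequency against the *line of equality* — temperature rise time
plus the minimal conduction latency from the skin.  Peaks above the line
imply a plateau-phase peak (SC); an onset burst marks a QC regardless of
where the peak falls.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Union

import numpy as np

__all__ = [
    "FiberMetadata",
    "SpikeTrain",
    "HeatStimulus",
    "IFSeries",
    "BurstParams",
    "HeatLabel",
    "FiberClass",
    "MechanoClass",
    "NOT_REACHED",
    "HeatClassification",
    "instantaneous_frequency",
    "median_smooth3",
    "time_of_peak_discharge",
    "detect_onset_burst",
    "classify_heat_response",
    "classify_by_cv",
    "von_frey_threshold",
    "classify_mechanosensitivity",
]


@dataclass(frozen=True)
class FiberMetadata:
    """Conduction and mechanosensitivity properties of one afferent fiber.

    Parameters
    ----------
    conduction_latency_skin_s:
        Minimal AP conduction time from transcutaneous electrical
        stimulation at the receptive field, in seconds.
    conduction_velocity_m_s:
        Conduction velocity at the nerve trunk (m/s).
    conduction_distance_cm:
        Distance from receptive field to recording electrode (cm).
    mech_threshold_bar:
        von Frey threshold (bar), or None if mechanically insensitive /
        not determined.
    """

    conduction_latency_skin_s: Optional[float] = None
    conduction_velocity_m_s: Optional[float] = None
    conduction_distance_cm: Optional[float] = None
    mech_threshold_bar: Optional[float] = None

    def __post_init__(self) -> None:
        if self.conduction_latency_skin_s is not None and self.conduction_latency_skin_s <= 0:
            raise ValueError("conduction latency must be positive")
        if self.conduction_velocity_m_s is not None and self.conduction_velocity_m_s <= 0:
            raise ValueError("conduction velocity must be positive")


@dataclass(frozen=True)
class SpikeTrain:
    """Ordered action-potential timestamps of one fiber.

    Timestamps are in seconds relative to a reference event (stimulus
    onset or injection start) and must be strictly increasing.  An empty
    train is allowed.
    """

    fiber_id: str
    timestamps: np.ndarray
    metadata: FiberMetadata = field(default_factory=FiberMetadata)

    def __post_init__(self) -> None:
        ts = np.asarray(self.timestamps, dtype=float)
        if ts.ndim != 1:
            raise ValueError("timestamps must be one-dimensional")
        if ts.size > 1 and not np.all(np.diff(ts) > 0):
            raise ValueError("timestamps must be strictly increasing")
        object.__setattr__(self, "timestamps", ts)

    def __len__(self) -> int:
        return self.timestamps.size

    def shifted(self, dt: float) -> "SpikeTrain":
        """Return a copy with all timestamps translated by ``dt`` seconds."""
        return replace(self, timestamps=self.timestamps + dt)


@dataclass(frozen=True)
class HeatStimulus:
    """Parametric stepped-heat waveform.

    Default matches the study protocol: skin pre-heated to 38 °C for 3 s,
    then rapidly raised (rise time ~200 ms) to 49 °C for a 3-s plateau.
    Time 0 is the start of the temperature rise.
    """

    baseline_temp_c: float = 38.0
    target_temp_c: float = 49.0
    baseline_duration_s: float = 3.0
    rise_time_s: float = 0.2
    plateau_duration_s: float = 3.0

    def __post_init__(self) -> None:
        if self.target_temp_c <= self.baseline_temp_c:
            raise ValueError("target temperature must exceed baseline")
        if self.rise_time_s <= 0 or self.plateau_duration_s <= 0:
            raise ValueError("rise time and plateau duration must be positive")


@dataclass(frozen=True)
class IFSeries:
    """Instantaneous-frequency series: one (time, Hz) point per interspike interval.

    The frequency 1/ISI is assigned to the later spike of each pair — it is
    only known once the second spike arrives.
    """

    times: np.ndarray
    frequencies: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        f = np.asarray(self.frequencies, dtype=float)
        if t.shape != f.shape or t.ndim != 1:
            raise ValueError("times and frequencies must be equal-length 1-D arrays")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly ascending")
        if np.any(f <= 0):
            raise ValueError("instantaneous frequencies must be positive")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "frequencies", f)

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class BurstParams:
    """Numeric definition of an onset burst and of adaptation.

    The study describes the QC onset burst only qualitatively; these
    defaults quantify it and are configurable.

    burst_window_s counts IF points up to ``rise_time + burst_window_s``
    past the (latency-corrected) stimulus onset; the discharge is
    *adapting* when the mean IF over the final half of the plateau falls
    below ``adaptation_ratio`` times the peak IF.
    """

    burst_min_spikes: int = 3
    burst_window_s: float = 0.2
    burst_min_freq_hz: float = 20.0
    adaptation_ratio: float = 0.5


class HeatLabel(str, enum.Enum):
    QC = "QC"
    SC = "SC"
    UNCLASSIFIED = "UNCLASSIFIED"


class FiberClass(str, enum.Enum):
    C = "C"
    A_DELTA = "A_DELTA"
    OUT_OF_RANGE = "OUT_OF_RANGE"


class MechanoClass(str, enum.Enum):
    MSA = "MSA"  # mechano-sensitive afferent
    MIA = "MIA"  # mechano-insensitive afferent


class _NotReached:
    """Sentinel: no von Frey filament reached the 2/4 response criterion."""

    _instance: Optional["_NotReached"] = None

    def __new__(cls) -> "_NotReached":
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "NOT_REACHED"


NOT_REACHED = _NotReached()


@dataclass(frozen=True)
class HeatClassification:
    """Outcome of the QC/SC decision for one fiber."""

    label: HeatLabel
    peak_time_s: Optional[float]
    equality_line_s: float
    burst_at_onset: bool
    diagnostics: IFSeries


def instantaneous_frequency(train: SpikeTrain) -> IFSeries:
    """Instantaneous discharge frequency 1/ISI versus time.

    For each consecutive spike pair (t_i, t_{i+1}) one point is produced
    at time t_{i+1} with frequency 1/(t_{i+1} − t_i).  A train with fewer
    than two spikes yields an empty series.

    Raises
    ------
    ValueError
        If the train contains duplicate timestamps (zero ISI).
    """
    ts = train.timestamps
    if ts.size < 2:
        return IFSeries(np.empty(0), np.empty(0))
    isi = np.diff(ts)
    if np.any(isi == 0):
        raise ValueError("duplicate timestamps: zero interspike interval")
    return IFSeries(ts[1:], 1.0 / isi)


def median_smooth3(series: IFSeries) -> IFSeries:
    """Three-point median smoothing of an IF series.

    Each interior point is replaced by the median of itself and its two
    neighbours; the first and last points pass through unchanged, as do
    series shorter than three points.  Times are untouched.
    """
    f = series.frequencies
    if f.size < 3:
        return series
    smoothed = f.copy()
    windows = np.stack([f[:-2], f[1:-1], f[2:]])
    smoothed[1:-1] = np.median(windows, axis=0)
    return IFSeries(series.times, smoothed)


def time_of_peak_discharge(series: IFSeries) -> float:
    """Time of the maximum (smoothed) instantaneous frequency.

    Ties are broken by the earliest occurrence, which is conservative
    toward an early (QC-like) peak.
    """
    if len(series) == 0:
        raise ValueError("no discharge: empty IF series")
    return float(series.times[int(np.argmax(series.frequencies))])


def detect_onset_burst(
    series: IFSeries,
    stimulus: HeatStimulus,
    params: BurstParams = BurstParams(),
    offset_s: float = 0.0,
) -> bool:
    """Detect a QC-style burst at the onset of the heat response.

    True iff at least ``burst_min_spikes`` IF points fall within
    ``[offset, offset + rise_time + burst_window]`` at frequencies of at
    least ``burst_min_freq`` **and** the onset discharge adapts: the mean
    IF over the final half of the plateau is below ``adaptation_ratio``
    times the peak IF of the burst window (no plateau-half points counts
    as fully adapted).  Adaptation is judged against the onset discharge
    itself — judging it against the global peak would let any fiber whose
    peak sits in the plateau "adapt" relative to its own late maximum.

    ``offset_s`` shifts the analysis origin to where the response can
    physically begin — the conduction latency from skin — since spike
    timestamps include conduction delay.
    """
    if len(series) == 0:
        return False
    t = series.times - offset_s
    f = series.frequencies
    win_end = stimulus.rise_time_s + params.burst_window_s
    in_window = (t >= 0) & (t <= win_end)
    early = in_window & (f >= params.burst_min_freq_hz)
    if int(np.count_nonzero(early)) < params.burst_min_spikes:
        return False
    onset_peak = float(f[in_window].max())
    half_start = stimulus.rise_time_s + stimulus.plateau_duration_s / 2.0
    half_end = stimulus.rise_time_s + stimulus.plateau_duration_s
    late = (t >= half_start) & (t <= half_end)
    late_mean = float(f[late].mean()) if np.any(late) else 0.0
    return late_mean < params.adaptation_ratio * onset_peak


def classify_heat_response(
    train: SpikeTrain,
    stimulus: HeatStimulus,
    meta: Optional[FiberMetadata] = None,
    tolerance_s: float = 0.1,
    burst_params: BurstParams = BurstParams(),
    onset_s: float = 0.0,
) -> HeatClassification:
    """Classify one CMH heat response as QC, SC, or unclassified.

    Let E = rise_time + conduction latency from skin (the line of
    equality) and P = time of peak discharge of the 3-point median
    smoothed IF series, both relative to stimulus onset (``onset_s`` in
    the train's time base).  The rule:

    * an onset burst → QC, even when P > E (the study reports three QC
      fibers above the line of equality);
    * otherwise P > E + tolerance → SC (plateau-phase peak);
    * otherwise |P − E| ≤ tolerance → UNCLASSIFIED (on the line);
    * otherwise (P < E − tolerance) → QC.

    Only spikes within the stimulus window [onset, onset + E + plateau]
    are analysed.  Trains with fewer than two such spikes are
    UNCLASSIFIED with empty diagnostics.
    """
    meta = meta if meta is not None else train.metadata
    latency = meta.conduction_latency_skin_s
    if latency is None:
        raise ValueError("conduction latency from skin is required for classification")
    equality = stimulus.rise_time_s + latency

    rel = train.timestamps - onset_s
    window_end = equality + stimulus.plateau_duration_s
    in_window = rel[(rel >= 0) & (rel <= window_end)]
    if in_window.size < 2:
        empty = IFSeries(np.empty(0), np.empty(0))
        return HeatClassification(HeatLabel.UNCLASSIFIED, None, equality, False, empty)

    windowed = SpikeTrain(train.fiber_id, in_window, meta)
    smoothed = median_smooth3(instantaneous_frequency(windowed))
    peak = time_of_peak_discharge(smoothed)
    burst = detect_onset_burst(smoothed, stimulus, burst_params, offset_s=latency)

    if burst:
        label = HeatLabel.QC
    elif peak > equality + tolerance_s:
        label = HeatLabel.SC
    elif abs(peak - equality) <= tolerance_s:
        label = HeatLabel.UNCLASSIFIED
    else:
        label = HeatLabel.QC
    return HeatClassification(label, peak, equality, burst, smoothed)


def classify_by_cv(cv_m_s: float) -> FiberClass:
    """Fiber class from conduction velocity: <2 m/s C, 2–20 m/s Aδ."""
    if cv_m_s <= 0:
        raise ValueError("conduction velocity must be positive")
    if cv_m_s < 2.0:
        return FiberClass.C
    if cv_m_s <= 20.0:
        return FiberClass.A_DELTA
    return FiberClass.OUT_OF_RANGE


def von_frey_threshold(
    responses: Mapping[float, int],
) -> Union[float, _NotReached]:
    """Mechanical threshold: smallest filament responding in ≥2 of 4 applications.

    ``responses`` maps filament stiffness (bar) to the number of positive
    responses out of four applications.  Returns NOT_REACHED if no
    filament qualifies.
    """
    for bar, count in responses.items():
        if not 0 <= count <= 4:
            raise ValueError(f"response count {count} for {bar} bar outside 0..4")
    qualifying = [bar for bar, count in responses.items() if count >= 2]
    if not qualifying:
        return NOT_REACHED
    return min(qualifying)


def classify_mechanosensitivity(
    threshold: Union[float, _NotReached],
) -> MechanoClass:
    """MSA if the von Frey threshold is at most 6 bar, MIA otherwise.

    A fiber with no threshold (NOT_REACHED) is mechano-insensitive by
    definition.  Exactly 6 bar is counted MSA (inclusive boundary).
    """
    if isinstance(threshold, _NotReached):
        return MechanoClass.MIA
    return MechanoClass.MSA if threshold <= 6.0 else MechanoClass.MIA
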