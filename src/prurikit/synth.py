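"""Synthetic cohorts with declared ground truth for every pipeline stage.

The generators emulate the study's data-generating conditions: QC heat
responses (onset burst during the ~200-ms temperature ramp, then adapting
discharge), SC responses (slow onset, peak in the 3-s plateau),
pruritogen-evoked discharge decaying over the 5-min observation window
with population means set to the reported cell means, vehicle injections
active only through spontaneous/artifact spikes, gLMS rating curves that
peak 1–2 min post-injection and decay over ~10–20 min (slower for
histamine-containing stimuli), and RNAscope puncta cohorts with
configurable marker co-expression probabilities.

Spike trains are inhomogeneous Poisson processes with deterministic rate
functions (the study reports only qualitative discharge shapes).  All
generators are driven by a ``numpy.random.Generator`` (or an int seed);
the same seed reproduces byte-identical outputs.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from .chemo import InjectionRecording
from .psycho import RATING_STEP_MIN, SESSION_MAX_MIN, SESSION_MIN_MIN, RatingSeries
from .spike import FiberMetadata, HeatStimulus, SpikeTrain
from .ish import NeuronPunctaRecord

__all__ = [
    "load_default_config",
    "CohortConfig",
    "generate_heat_train",
    "generate_heat_cohort",
    "generate_injection",
    "generate_injection_pair",
    "generate_chemo_cohort",
    "generate_ratings",
    "generate_rating_cohort",
    "generate_area_table",
    "generate_puncta_cohort",
]

RNGLike = Union[int, np.random.Generator]


def _rng(seed: RNGLike) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def load_default_config() -> dict:
    """Generator defaults (rates, targets, probabilities) from the packaged YAML."""
    ref = importlib.resources.files("prurikit.data").joinpath("defaults.yaml")
    with ref.open("r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)


_DEFAULTS = load_default_config()


@dataclass(frozen=True)
class CohortConfig:
    """Sizes and seed of a full synthetic study."""

    n_qc: int = 29
    n_sc: int = 31
    n_subjects: int = 29
    n_donors: int = 4
    neurons_per_donor: int = 150
    seed: int = 0
    params: dict = field(default_factory=load_default_config)


# --------------------------------------------------------------------------
# heat responses


def _sample_inhomogeneous(
    rate_fn: Callable[[np.ndarray], np.ndarray],
    t_max: float,
    rate_max: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Thinning sampler for an inhomogeneous Poisson process on [0, t_max]."""
    if rate_max <= 0:
        return np.empty(0)
    n = rng.poisson(rate_max * t_max)
    cand = np.sort(rng.uniform(0.0, t_max, size=n))
    keep = rng.uniform(0.0, rate_max, size=n) < rate_fn(cand)
    ts = cand[keep]
    # enforce strictly increasing timestamps (duplicate draws are measure-zero
    # in theory but not in floating point)
    if ts.size > 1:
        ts = ts[np.concatenate([[True], np.diff(ts) > 1e-9])]
    return ts


def generate_heat_train(
    fiber_type: str,
    stimulus: HeatStimulus = HeatStimulus(),
    latency_s: Optional[float] = None,
    rate_scale: float = 1.0,
    rng: RNGLike = 0,
    fiber_id: str = "fiber",
    params: Optional[dict] = None,
) -> Tuple[SpikeTrain, str]:
    """One synthetic heat response with its ground-truth label.

    QC: boxcar burst during the temperature ramp followed by exponential
    adaptation over the plateau.  SC: gamma-shaped rate peaking
    ``peak_after_rise_s`` into the plateau, no onset burst.  Spike
    timestamps include the conduction latency from skin (drawn uniformly
    from the configured range when not given).  ``rate_scale`` scales the
    whole rate function (0 gives an empty train).
    """
    fiber_type = fiber_type.upper()
    if fiber_type not in ("QC", "SC"):
        raise ValueError("fiber_type must be 'QC' or 'SC'")
    p = (params or _DEFAULTS)["heat"][fiber_type]
    lat_cfg = (params or _DEFAULTS)["latency"]
    rng = _rng(rng)
    if latency_s is None:
        latency_s = float(rng.uniform(lat_cfg["min_s"], lat_cfg["max_s"]))
    rise = stimulus.rise_time_s
    plateau = stimulus.plateau_duration_s

    if fiber_type == "QC":
        r0 = p["burst_rate_hz"] * rate_scale
        t_burst = p["burst_start_frac"] * rise
        tau = p["adapt_tau_s"]

        def rate(t: np.ndarray) -> np.ndarray:
            r = np.zeros_like(t)
            in_burst = (t >= t_burst) & (t <= rise)
            r[in_burst] = r0
            in_plateau = (t > rise) & (t <= rise + plateau)
            r[in_plateau] = r0 * np.exp(-(t[in_plateau] - rise) / tau)
            return r

        rate_max = r0
    else:
        r0 = p["max_rate_hz"] * rate_scale
        tp = rise + p["peak_after_rise_s"]
        a = p["shape"]

        def rate(t: np.ndarray) -> np.ndarray:
            x = np.clip(t / tp, 1e-12, None)
            r = r0 * x**a * np.exp(a * (1.0 - x))
            r[(t < 0) | (t > rise + plateau)] = 0.0
            return r

        rate_max = r0

    response = _sample_inhomogeneous(rate, rise + plateau, rate_max, rng)
    meta = FiberMetadata(conduction_latency_skin_s=latency_s)
    return SpikeTrain(fiber_id, latency_s + response, meta), fiber_type


def generate_heat_cohort(
    n_qc: int,
    n_sc: int,
    stimulus: HeatStimulus = HeatStimulus(),
    rng: RNGLike = 0,
    params: Optional[dict] = None,
) -> List[Tuple[SpikeTrain, str]]:
    """A labelled cohort of QC and SC heat responses."""
    rng = _rng(rng)
    cohort = []
    for i in range(n_qc):
        cohort.append(
            generate_heat_train("QC", stimulus, rng=rng, fiber_id=f"QC{i:03d}",
                                params=params)
        )
    for i in range(n_sc):
        cohort.append(
            generate_heat_train("SC", stimulus, rng=rng, fiber_id=f"SC{i:03d}",
                                params=params)
        )
    return cohort


# --------------------------------------------------------------------------
# pruritogen injections


def _homogeneous(rate: float, duration: float, rng: np.random.Generator) -> np.ndarray:
    n = rng.poisson(rate * duration)
    return np.sort(rng.uniform(0.0, duration, size=n))


def generate_injection(
    fiber_type: str,
    compound: str,
    rng: RNGLike = 0,
    fiber_id: str = "fiber",
    amplitude: Optional[float] = None,
    params: Optional[dict] = None,
) -> InjectionRecording:
    """One intradermal injection recording for one fiber.

    Spontaneous activity is homogeneous Poisson throughout (baseline and
    post-injection); vehicle compounds evoke nothing beyond injection
    artifacts.  For pruritogens the evoked post-injection rate is
    A/τ·e^(−t/τ), normalised so the *expected* evoked count inside the
    observation window equals the amplitude A.  By default A is 0 with
    probability 1 − response_prob and gamma-distributed for responders,
    scaled so the population mean equals the configured target net APs.
    """
    cfg = (params or _DEFAULTS)["injection"]
    rng = _rng(rng)
    fiber_type = fiber_type.upper()
    inj_dur = cfg["injection_duration_s"]
    obs = cfg["observation_s"]
    lam_s = cfg["spontaneous_rate_hz"]

    baseline = int(rng.poisson(lam_s * 60.0))
    artifact = _homogeneous(cfg["artifact_spikes_mean"] / inj_dur, inj_dur, rng)
    spont = inj_dur + _homogeneous(lam_s, obs, rng)

    if compound in cfg["vehicles"]:
        evoked = np.empty(0)
    else:
        if amplitude is None:
            prob = cfg["response_prob"][fiber_type][compound]
            target = cfg["target_net_aps"][fiber_type][compound]
            shape = cfg["amplitude_shape"]
            if rng.uniform() < prob:
                amplitude = float(rng.gamma(shape, (target / prob) / shape))
            else:
                amplitude = 0.0
        tau = cfg["decay_tau_s"][fiber_type][compound]
        # normalise so the expected count inside the window is `amplitude`
        n_mean = amplitude / (1.0 - np.exp(-obs / tau))
        n = rng.poisson(n_mean)
        t = -tau * np.log(rng.uniform(size=n))
        evoked = inj_dur + np.sort(t[t <= obs])

    post = np.sort(np.concatenate([artifact, spont, evoked]))
    if post.size > 1:
        post = post[np.concatenate([[True], np.diff(post) > 1e-9])]
    return InjectionRecording(
        fiber_id=fiber_id,
        compound=compound,
        baseline_count=baseline,
        injection_interval=(0.0, inj_dur),
        post_spikes=post,
        observation_s=obs + inj_dur,
    )


def generate_injection_pair(
    fiber_type: str,
    compound: str,
    rng: RNGLike = 0,
    fiber_id: str = "fiber",
    vehicle: str = "ECF",
    params: Optional[dict] = None,
) -> Tuple[InjectionRecording, InjectionRecording]:
    """A pruritogen recording and its matching vehicle recording for one fiber."""
    rng = _rng(rng)
    veh = generate_injection(fiber_type, vehicle, rng, fiber_id, params=params)
    prur = generate_injection(fiber_type, compound, rng, fiber_id, params=params)
    return prur, veh


def generate_chemo_cohort(
    n_qc: int = 29,
    n_sc: int = 31,
    compounds: Sequence[str] = ("ALA", "BAM8_22"),
    rng: RNGLike = 0,
    params: Optional[dict] = None,
) -> pd.DataFrame:
    """Net responses of a labelled QC/SC cohort to each compound (tidy table).

    Each fiber receives one vehicle injection followed by every pruritogen;
    columns: fiber_id, fiber_type, compound, net_aps, responsive.
    """
    from .chemo import net_response

    rng = _rng(rng)
    rows = []
    for fiber_type, n in (("QC", n_qc), ("SC", n_sc)):
        for i in range(n):
            fid = f"{fiber_type}{i:03d}"
            veh = generate_injection(fiber_type, "ECF", rng, fid, params=params)
            for compound in compounds:
                prur = generate_injection(fiber_type, compound, rng, fid, params=params)
                net = net_response(prur, veh)
                rows.append(
                    {
                        "fiber_id": fid,
                        "fiber_type": fiber_type,
                        "compound": compound,
                        "net_aps": net.net_aps,
                        "responsive": net.responsive,
                    }
                )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# gLMS ratings and dysesthesia areas


def generate_ratings(
    stimulus: str,
    subject_id: str = "S00",
    gain: Optional[float] = None,
    rng: RNGLike = 0,
    params: Optional[dict] = None,
) -> List[RatingSeries]:
    """One subject's itch / pricking-stinging / burning rating series.

    The mean percept rises with time constant ``rise_tau_min`` (peak
    between 1 and 2 min) and decays exponentially after ``decay_onset_min``
    — more slowly for histamine-containing stimuli.  A log-normal subject
    gain multiplies the curve; Gaussian rating noise is added; percepts
    below the rating floor register as exact zeros.  The session follows
    the protocol stop rule: at least 5 min, at most 20 min, ending once
    all qualities show three successive zeros.
    """
    cfg = (params or _DEFAULTS)["ratings"]
    rng = _rng(rng)
    if gain is None:
        gain = float(rng.lognormal(0.0, cfg["gain_sigma"]))
    grid = np.arange(RATING_STEP_MIN, SESSION_MAX_MIN + 1e-9, RATING_STEP_MIN)
    series: Dict[str, np.ndarray] = {}
    for quality in ("itch", "pricking_stinging", "burning"):
        peak = cfg["mean_peak"][quality][stimulus]
        tau = (
            cfg["itch_decay_tau_min"][stimulus]
            if quality == "itch"
            else cfg["pain_decay_tau_min"]
        )
        mean = (
            peak
            * (1.0 - np.exp(-grid / cfg["rise_tau_min"]))
            * np.exp(-np.maximum(0.0, grid - cfg["decay_onset_min"]) / tau)
        )
        # rating noise scales with the subject's gain: a subject who feels
        # nothing rates a flat zero
        percept = gain * (mean + rng.normal(0.0, cfg["noise_sd"], size=grid.size))
        percept[percept < cfg["rating_floor"]] = 0.0
        series[quality] = np.clip(percept, 0.0, 100.0)

    # stop rule: earliest grid point ≥ 5 min at which every quality has
    # shown three successive zeros
    stacked = np.stack(list(series.values()))
    n_min = int(round(SESSION_MIN_MIN / RATING_STEP_MIN))
    stop = grid.size
    for i in range(n_min, grid.size + 1):
        if i >= 3 and np.all(stacked[:, i - 3 : i] == 0):
            stop = i
            break
    return [
        RatingSeries(subject_id, stimulus, q, grid[:stop], series[q][:stop])
        for q in series
    ]


def generate_rating_cohort(
    n_subjects: int = 29,
    stimuli: Sequence[str] = ("ALA", "BAM", "HIS", "BAM+ALA", "BAM+ALA+HIS"),
    rng: RNGLike = 0,
    params: Optional[dict] = None,
) -> List[RatingSeries]:
    """A full psychophysics cohort: every subject rates every stimulus."""
    rng = _rng(rng)
    cfg = (params or _DEFAULTS)["ratings"]
    out: List[RatingSeries] = []
    for s in range(n_subjects):
        gain = float(rng.lognormal(0.0, cfg["gain_sigma"]))
        for stim in stimuli:
            out.extend(
                generate_ratings(stim, f"S{s:02d}", gain=gain, rng=rng, params=params)
            )
    return out


def generate_area_table(
    n_subjects: int = 29,
    stimuli: Sequence[str] = ("ALA", "BAM", "HIS", "BAM+ALA", "BAM+ALA+HIS"),
    rng: RNGLike = 0,
    params: Optional[dict] = None,
) -> pd.DataFrame:
    """Dysesthesia / wheal / flare areas (cm²) per subject × stimulus × measure.

    Log-normal areas around a per-measure median, multiplied for
    histamine-containing stimuli (wheal and flare are strongly
    histamine-driven in skin).
    """
    cfg = (params or _DEFAULTS)["areas"]
    rng = _rng(rng)
    rows = []
    for s in range(n_subjects):
        subj_gain = rng.lognormal(0.0, 0.3)
        for stim in stimuli:
            his = "HIS" in stim
            for measure, base in cfg["base_cm2"].items():
                median = base * (cfg["his_multiplier"] if his else 1.0)
                area = subj_gain * median * rng.lognormal(0.0, cfg["sigma"])
                rows.append(
                    {
                        "subject_id": f"S{s:02d}",
                        "stimulus": stim,
                        "measure": measure,
                        "area_cm2": float(area),
                    }
                )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# ISH puncta cohorts


def generate_puncta_cohort(
    n_donors: int = 4,
    neurons_per_donor: int = 150,
    species: Optional[str] = None,
    joint: Optional[Sequence[dict]] = None,
    rng: RNGLike = 0,
    params: Optional[dict] = None,
) -> List[NeuronPunctaRecord]:
    """Per-neuron puncta counts with a configured joint marker-state distribution.

    Each neuron's marker states are drawn from the joint distribution over
    the 2³ combinations; puncta counts come from well-separated
    negative-binomial distributions for positive and negative states, so
    thresholding recovers the states with a small known error rate.
    """
    cfg = (params or _DEFAULTS)["puncta"]
    rng = _rng(rng)
    species = species or cfg["species"]
    joint = list(joint if joint is not None else cfg["joint"])
    markers = [k for k in joint[0] if k != "p"]
    probs = np.array([cell["p"] for cell in joint], dtype=float)
    if probs.min() < 0 or abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("inconsistent joint probabilities (must be ≥0 and sum to 1)")

    def _nb(mean: float, shape: float, size: int) -> np.ndarray:
        return rng.negative_binomial(shape, shape / (shape + mean), size=size)

    records: List[NeuronPunctaRecord] = []
    for d in range(n_donors):
        donor = f"D{d + 1}"
        states = rng.choice(len(joint), size=neurons_per_donor, p=probs)
        for i, cell_idx in enumerate(states):
            cell = joint[cell_idx]
            for marker in markers:
                if cell[marker]:
                    puncta = int(_nb(cfg["positive_mean"], cfg["positive_shape"], 1)[0])
                else:
                    puncta = int(_nb(cfg["negative_mean"], cfg["negative_shape"], 1)[0])
                records.append(
                    NeuronPunctaRecord(
                        species=species,
                        donor_id=donor,
                        section_id="sec1",
                        neuron_id=f"{donor}_n{i:04d}",
                        marker=marker,
                        puncta=puncta,
                    )
                )
    return records
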