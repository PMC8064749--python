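"""Shared fixtures: deterministic archetype spike trains and small cohorts."""

import numpy as np
import pytest

from prurikit.spike import FiberMetadata, HeatStimulus, SpikeTrain

DEFAULT_STIMULUS = HeatStimulus()  # 38→49 °C, 0.2 s rise, 3 s plateau


@pytest.fixture
def stimulus() -> HeatStimulus:
    return DEFAULT_STIMULUS


def make_qc_archetype(latency: float = 0.3) -> SpikeTrain:
    """Noise-free QC response: 50-Hz onset burst in the ramp, then adapting."""
    burst = latency + np.arange(0.06, 0.201, 0.02)
    adapt = latency + 0.2 + np.cumsum([0.05, 0.1, 0.2, 0.4, 0.8, 1.2])
    meta = FiberMetadata(conduction_latency_skin_s=latency)
    return SpikeTrain("qc_arch", np.concatenate([burst, adapt]), meta)


def make_sc_archetype(latency: float = 0.3) -> SpikeTrain:
    """Noise-free SC response: discharge ramping to a plateau-phase peak, no burst."""
    rel = np.array([0.5, 0.9, 1.2, 1.4, 1.55, 1.65, 1.72, 1.78, 1.9, 2.1, 2.4, 2.8])
    meta = FiberMetadata(conduction_latency_skin_s=latency)
    return SpikeTrain("sc_arch", latency + rel, meta)


def make_online_archetype(latency: float = 0.3) -> SpikeTrain:
    """Peak discharge exactly on the line of equality, no burst (unclassified)."""
    # smoothed IF peaks (first occurrence) exactly at rise + latency = 0.5 s
    ts = np.array([0.0, 0.3, 0.5, 0.7, 1.2])
    meta = FiberMetadata(conduction_latency_skin_s=latency)
    return SpikeTrain("online_arch", ts, meta)


@pytest.fixture
def qc_archetype() -> SpikeTrain:
    return make_qc_archetype()


@pytest.fixture
def sc_archetype() -> SpikeTrain:
    return make_sc_archetype()
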