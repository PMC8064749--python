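"""RNAscope in-situ-hybridization puncta counts → positivity calls and co-expression.

A DRG neuron is called positive for a marker when its puncta count strictly
exceeds a per-species threshold (human: >5 puncta per cell; macaque: >3).
Co-expression between two markers is reported both as mean ± SEM of the
per-donor percentages (n − 1 denominator across donors — three DRG sections
stand in for donors in the macaque panel) and as the aggregated count over
all donors pooled; the two generally differ when donors are unbalanced.
Three-marker panels (MRGPRD, MRGPRX1, TRPV1) are summarised as the seven
Venn regions plus the triple-negative count.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "PUNCTA_THRESHOLDS",
    "NeuronPunctaRecord",
    "CoexpressionSummary",
    "VennSummary",
    "call_positive",
    "positivity_table",
    "coexpression_summary",
    "venn_summary",
]

#: Puncta-per-cell positivity thresholds (strict: positive iff puncta > threshold).
PUNCTA_THRESHOLDS: Dict[str, int] = {"human": 5, "macaque": 3}


@dataclass(frozen=True)
class NeuronPunctaRecord:
    species: str
    donor_id: str
    section_id: str
    neuron_id: str
    marker: str
    puncta: int

    def __post_init__(self) -> None:
        if self.puncta < 0:
            raise ValueError("puncta count must be non-negative")


@dataclass(frozen=True)
class CoexpressionSummary:
    """Fraction of marker-A-positive neurons that are also positive for marker B."""

    marker_a: str
    marker_b: str
    per_donor_percent: Dict[str, float]
    mean_percent: float
    sem_percent: Optional[float]
    double_positive: int
    a_positive: int

    @property
    def aggregated_percent(self) -> float:
        return 100.0 * self.double_positive / self.a_positive


@dataclass(frozen=True)
class VennSummary:
    """Counts of the 2³ marker-combination regions for a three-marker panel."""

    markers: Tuple[str, str, str]
    region_counts: Dict[Tuple[bool, bool, bool], int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.region_counts.values())

    def count(self, **flags: bool) -> int:
        key = tuple(bool(flags[m]) for m in self.markers)
        return self.region_counts.get(key, 0)


def call_positive(puncta: int, threshold: int) -> bool:
    """Positive iff strictly more than ``threshold`` puncta per cell."""
    if puncta < 0:
        raise ValueError("puncta count must be non-negative")
    return puncta > threshold


def positivity_table(
    records: Sequence[NeuronPunctaRecord],
    thresholds: Optional[Dict[str, int]] = None,
) -> pd.DataFrame:
    """One row per neuron, one boolean column per marker.

    The threshold is looked up per species (:data:`PUNCTA_THRESHOLDS` by
    default).  Raises if any neuron is missing one of the panel's markers
    or is recorded twice for the same marker.
    """
    thresholds = PUNCTA_THRESHOLDS if thresholds is None else thresholds
    df = pd.DataFrame([r.__dict__ for r in records])
    if df.empty:
        raise ValueError("no puncta records")
    dup = df.duplicated(["species", "donor_id", "section_id", "neuron_id", "marker"])
    if dup.any():
        raise ValueError("duplicate marker record for a neuron")
    df["positive"] = [
        call_positive(p, thresholds[sp]) for p, sp in zip(df["puncta"], df["species"])
    ]
    wide = df.pivot_table(
        index=["species", "donor_id", "section_id", "neuron_id"],
        columns="marker",
        values="positive",
        aggfunc="first",
    )
    if wide.isna().any().any():
        missing = wide.index[wide.isna().any(axis=1)][:3]
        raise ValueError(f"neurons missing a marker record, e.g. {list(missing)}")
    return wide.astype(bool).reset_index()


def coexpression_summary(
    records: Sequence[NeuronPunctaRecord],
    marker_a: str,
    marker_b: str,
    thresholds: Optional[Dict[str, int]] = None,
) -> CoexpressionSummary:
    """P(B+ | A+) per donor (mean ± SEM) and aggregated over donors.

    Donors with zero A-positive neurons are excluded from the per-donor
    mean (logged) but their neurons still enter the aggregated counts.
    SEM uses the n−1 denominator across donors and is reported as None
    for a single donor.
    """
    wide = positivity_table(records, thresholds)
    if marker_a not in wide.columns or marker_b not in wide.columns:
        raise ValueError(f"panel lacks marker {marker_a!r} or {marker_b!r}")
    per_donor: Dict[str, float] = {}
    for donor, grp in wide.groupby("donor_id"):
        n_a = int(grp[marker_a].sum())
        if n_a == 0:
            warnings.warn(
                f"donor {donor}: no {marker_a}-positive neurons, excluded from mean",
                stacklevel=2,
            )
            continue
        n_ab = int((grp[marker_a] & grp[marker_b]).sum())
        per_donor[donor] = 100.0 * n_ab / n_a
    if not per_donor:
        raise ValueError(f"no donor has any {marker_a}-positive neuron")
    values = np.array(list(per_donor.values()))
    mean = float(values.mean())
    sem = float(values.std(ddof=1) / np.sqrt(values.size)) if values.size > 1 else None
    a_pos = int(wide[marker_a].sum())
    double = int((wide[marker_a] & wide[marker_b]).sum())
    return CoexpressionSummary(
        marker_a, marker_b, per_donor, mean, sem, double, a_pos
    )


def venn_summary(
    records: Sequence[NeuronPunctaRecord],
    panel: Sequence[str] = ("MRGPRD", "MRGPRX1", "TRPV1"),
    thresholds: Optional[Dict[str, int]] = None,
) -> VennSummary:
    """Region counts of the three-marker Venn diagram (plus triple-negatives)."""
    if len(panel) != 3:
        raise ValueError("venn_summary requires a three-marker panel")
    wide = positivity_table(records, thresholds)
    for m in panel:
        if m not in wide.columns:
            raise ValueError(f"panel lacks marker {m!r}")
    counts: Dict[Tuple[bool, bool, bool], int] = {}
    for combo in itertools.product([False, True], repeat=3):
        mask = np.ones(len(wide), dtype=bool)
        for m, flag in zip(panel, combo):
            mask &= wide[m].to_numpy() == flag
        counts[combo] = int(mask.sum())
    return VennSummary(tuple(panel), counts)
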