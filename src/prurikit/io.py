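"""CSV schemas, validated readers/writers, configuration, and the pipeline driver.

All interchange is plain UTF-8 CSV with a header row and '.' decimal
separator, so fixtures stay hand-inspectable and integer counts round-trip
bit-exactly.  ``run_pipeline`` chains the stages — simulate → classify →
score → statistics → psychophysics → ISH — and writes tidy outputs plus a
run log recording the seed and a hash of the configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import chemo, ish, psycho, spike, synth
from .stats import TestResult

__all__ = [
    "SCHEMAS",
    "TableValidationError",
    "read_table",
    "write_table",
    "PipelineConfig",
    "simulate_inputs",
    "run_pipeline",
]

logger = logging.getLogger("prurikit")

#: column name → dtype kind ('f' float, 'i' int, 's' string) per schema
SCHEMAS: Dict[str, Dict[str, str]] = {
    "spikes": {"recording_id": "s", "fiber_id": "s", "event": "s", "t_s": "f"},
    "stimuli": {
        "recording_id": "s",
        "event": "s",
        "baseline_temp_c": "f",
        "target_temp_c": "f",
        "rise_s": "f",
        "plateau_s": "f",
        "conduction_latency_s": "f",
    },
    "injections": {
        "fiber_id": "s",
        "compound": "s",
        "baseline_aps_60s": "i",
        "inj_start_s": "f",
        "inj_end_s": "f",
        "observation_s": "f",
    },
    "ratings": {
        "subject_id": "s",
        "stimulus": "s",
        "quality": "s",
        "time_min": "f",
        "rating": "f",
    },
    "areas": {"subject_id": "s", "stimulus": "s", "measure": "s", "area_cm2": "f"},
    "puncta": {
        "species": "s",
        "donor_id": "s",
        "section_id": "s",
        "neuron_id": "s",
        "marker": "s",
        "puncta": "i",
    },
}

_DTYPES = {"f": float, "i": "Int64", "s": str}


class TableValidationError(ValueError):
    """Raised when a CSV fails schema validation; carries row-level errors."""

    def __init__(self, path, errors: List[str]):
        self.errors = errors
        super().__init__(f"{path}: {len(errors)} invalid rows: " + "; ".join(errors[:5]))


def read_table(path, schema: str) -> pd.DataFrame:
    """Read and validate a CSV against a named schema.

    Raises immediately on missing columns; numeric parse failures are
    collected with 1-based data line numbers and raised together.
    """
    if schema not in SCHEMAS:
        raise KeyError(f"unknown schema {schema!r}")
    spec_cols = SCHEMAS[schema]
    df = pd.read_csv(path, dtype=str)
    missing = set(spec_cols) - set(df.columns)
    if missing:
        raise TableValidationError(path, [f"missing column(s): {sorted(missing)}"])
    errors: List[str] = []
    out = {}
    for col, kind in spec_cols.items():
        if kind == "s":
            out[col] = df[col].astype(str)
            continue
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[parsed.isna() & df[col].notna()]
        for i in bad:
            errors.append(f"line {i + 1}, column {col!r}: cannot parse {df.loc[i, col]!r}")
        if kind == "i":
            nonint = parsed.dropna() % 1 != 0
            for i in parsed.dropna().index[nonint]:
                errors.append(f"line {i + 1}, column {col!r}: not an integer")
        out[col] = parsed
    if errors:
        raise TableValidationError(path, errors)
    result = pd.DataFrame(out)[list(spec_cols)]
    for col, kind in spec_cols.items():
        result[col] = result[col].astype(_DTYPES[kind])
    return result


def write_table(df: pd.DataFrame, path, schema: Optional[str] = None) -> None:
    """Write a tidy CSV (UTF-8, '.' decimals); column order fixed by schema if given."""
    if schema is not None:
        df = df[list(SCHEMAS[schema])]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


@dataclass
class PipelineConfig:
    """Everything the pipeline needs: analysis parameters, cohort sizes, paths, seed."""

    seed: int = 0
    out_dir: str = "prurikit_out"
    # classification
    tolerance_s: float = 0.1
    burst_min_spikes: int = 3
    burst_window_s: float = 0.2
    burst_min_freq_hz: float = 20.0
    adaptation_ratio: float = 0.5
    # response scoring
    response_window_s: float = 300.0
    responsive_threshold_aps: float = 10.0
    bin_s: float = 10.0
    # ISH
    puncta_thresholds: Dict[str, int] = field(
        default_factory=lambda: dict(ish.PUNCTA_THRESHOLDS)
    )
    # cohort sizes for simulation
    n_qc: int = 29
    n_sc: int = 31
    n_subjects: int = 29
    n_donors: int = 4
    neurons_per_donor: int = 150

    def __post_init__(self) -> None:
        for name in (
            "tolerance_s",
            "burst_window_s",
            "burst_min_freq_hz",
            "response_window_s",
            "responsive_threshold_aps",
            "bin_s",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if any(v <= 0 for v in self.puncta_thresholds.values()):
            raise ValueError("puncta thresholds must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def burst_params(self) -> spike.BurstParams:
        return spike.BurstParams(
            burst_min_spikes=self.burst_min_spikes,
            burst_window_s=self.burst_window_s,
            burst_min_freq_hz=self.burst_min_freq_hz,
            adaptation_ratio=self.adaptation_ratio,
        )


# --------------------------------------------------------------------------
# simulation → CSV inputs


def simulate_inputs(config: PipelineConfig, out_dir=None) -> Dict[str, Path]:
    """Generate a full synthetic study and write every input CSV schema.

    Writes spikes.csv (heat + injection events), stimuli.csv,
    injections.csv, ratings.csv, areas.csv, puncta.csv, and
    truth_labels.csv with the generator's ground-truth fiber types.
    """
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    stimulus = spike.HeatStimulus()

    spikes_rows: List[dict] = []
    stim_rows: List[dict] = []
    inj_rows: List[dict] = []
    truth_rows: List[dict] = []

    cohort = synth.generate_heat_cohort(config.n_qc, config.n_sc, stimulus, rng)
    for train, label in cohort:
        rec = f"{train.fiber_id}:heat_step"
        for t in train.timestamps:
            spikes_rows.append(
                {"recording_id": rec, "fiber_id": train.fiber_id,
                 "event": "heat_step", "t_s": t}
            )
        stim_rows.append(
            {
                "recording_id": rec,
                "event": "heat_step",
                "baseline_temp_c": stimulus.baseline_temp_c,
                "target_temp_c": stimulus.target_temp_c,
                "rise_s": stimulus.rise_time_s,
                "plateau_s": stimulus.plateau_duration_s,
                "conduction_latency_s": train.metadata.conduction_latency_skin_s,
            }
        )
        truth_rows.append({"fiber_id": train.fiber_id, "true_type": label})

        for compound in ("ECF", "ALA", "BAM8_22"):
            rec_inj = synth.generate_injection(label, compound, rng, train.fiber_id)
            event = f"inj_{compound}"
            rid = f"{train.fiber_id}:{event}"
            for t in rec_inj.post_spikes:
                spikes_rows.append(
                    {"recording_id": rid, "fiber_id": train.fiber_id,
                     "event": event, "t_s": t}
                )
            inj_rows.append(
                {
                    "fiber_id": train.fiber_id,
                    "compound": compound,
                    "baseline_aps_60s": rec_inj.baseline_count,
                    "inj_start_s": rec_inj.injection_interval[0],
                    "inj_end_s": rec_inj.injection_interval[1],
                    "observation_s": rec_inj.observation_s,
                }
            )

    ratings = synth.generate_rating_cohort(config.n_subjects, rng=rng)
    rating_rows = [
        {"subject_id": s.subject_id, "stimulus": s.stimulus, "quality": s.quality,
         "time_min": t, "rating": m}
        for s in ratings
        for t, m in zip(s.times_min, s.magnitudes)
    ]
    areas = synth.generate_area_table(config.n_subjects, rng=rng)
    puncta = synth.generate_puncta_cohort(
        config.n_donors, config.neurons_per_donor, rng=rng
    )
    puncta_rows = [r.__dict__ for r in puncta]

    paths = {}
    for name, rows, schema in (
        ("spikes", spikes_rows, "spikes"),
        ("stimuli", stim_rows, "stimuli"),
        ("injections", inj_rows, "injections"),
        ("ratings", rating_rows, "ratings"),
        ("puncta", puncta_rows, "puncta"),
    ):
        p = out / f"{name}.csv"
        write_table(pd.DataFrame(rows), p, schema)
        paths[name] = p
    p = out / "areas.csv"
    write_table(areas, p, "areas")
    paths["areas"] = p
    p = out / "truth_labels.csv"
    write_table(pd.DataFrame(truth_rows), p)
    paths["truth_labels"] = p
    return paths


# --------------------------------------------------------------------------
# analysis stages on CSV inputs


def _stats_rows(results: Sequence[TestResult], family: str) -> List[dict]:
    return [
        {
            "family": family,
            "method": r.method,
            "effect": r.effect,
            "statistic": r.statistic,
            "df": "x".join(f"{d:g}" for d in r.df),
            "p_value": r.p_value,
        }
        for r in results
    ]


def classify_stage(in_dir, config: PipelineConfig) -> pd.DataFrame:
    """Classify every heat recording in spikes.csv / stimuli.csv as QC/SC."""
    in_dir = Path(in_dir)
    spikes = read_table(in_dir / "spikes.csv", "spikes")
    stimuli = read_table(in_dir / "stimuli.csv", "stimuli")
    heat = spikes[spikes["event"] == "heat_step"]
    rows = []
    for _, stim_row in stimuli.iterrows():
        fiber_spikes = heat[heat["recording_id"] == stim_row["recording_id"]]
        fid = stim_row["recording_id"].split(":")[0]
        stim = spike.HeatStimulus(
            baseline_temp_c=stim_row["baseline_temp_c"],
            target_temp_c=stim_row["target_temp_c"],
            rise_time_s=stim_row["rise_s"],
            plateau_duration_s=stim_row["plateau_s"],
        )
        meta = spike.FiberMetadata(
            conduction_latency_skin_s=stim_row["conduction_latency_s"]
        )
        train = spike.SpikeTrain(fid, np.sort(fiber_spikes["t_s"].to_numpy()), meta)
        cls = spike.classify_heat_response(
            train, stim, meta, tolerance_s=config.tolerance_s,
            burst_params=config.burst_params(),
        )
        rows.append(
            {
                "fiber_id": fid,
                "label": cls.label.value,
                "peak_time_s": cls.peak_time_s,
                "equality_line_s": cls.equality_line_s,
                "burst_at_onset": cls.burst_at_onset,
            }
        )
    return pd.DataFrame(rows)


def score_stage(in_dir, config: PipelineConfig, labels: pd.DataFrame):
    """Net responses, time courses and the electrophysiology statistics."""
    in_dir = Path(in_dir)
    spikes = read_table(in_dir / "spikes.csv", "spikes")
    injections = read_table(in_dir / "injections.csv", "injections")

    recs: Dict[tuple, chemo.InjectionRecording] = {}
    for _, row in injections.iterrows():
        event = f"inj_{row['compound']}"
        sel = spikes[(spikes["fiber_id"] == row["fiber_id"]) & (spikes["event"] == event)]
        recs[(row["fiber_id"], row["compound"])] = chemo.InjectionRecording(
            fiber_id=row["fiber_id"],
            compound=row["compound"],
            baseline_count=int(row["baseline_aps_60s"]),
            injection_interval=(row["inj_start_s"], row["inj_end_s"]),
            post_spikes=sel["t_s"].to_numpy(),
            observation_s=row["observation_s"],
        )

    compounds = sorted({c for (_, c) in recs if c not in ("ECF", "BAM8_18")})
    net_rows, tc_rows = [], []
    nets: Dict[str, List[chemo.NetResponse]] = {c: [] for c in compounds}
    for (fid, compound), rec in recs.items():
        if compound in ("ECF", "BAM8_18"):
            continue
        veh = recs.get((fid, "ECF")) or recs.get((fid, "BAM8_18"))
        if veh is None:
            logger.warning("fiber %s: no vehicle recording, skipped", fid)
            continue
        net = chemo.net_response(rec, veh, window_s=config.response_window_s)
        nets[compound].append(net)
        net_rows.append(dataclasses.asdict(net))
        tc = chemo.bin_time_course(rec, bin_s=config.bin_s,
                                   duration_s=config.response_window_s)
        for lo, count in zip(tc.bin_edges[:-1], tc.counts):
            tc_rows.append(
                {"fiber_id": fid, "compound": compound, "bin_start_s": lo,
                 "count": int(count)}
            )

    stats_rows: List[dict] = []
    net_df = pd.DataFrame(net_rows)
    if len(compounds) == 2:
        a, b = compounds
        wide = net_df.pivot_table(index="fiber_id", columns="compound",
                                  values="net_aps").dropna()
        t_res = chemo.paired_t(wide[a].to_numpy(), wide[b].to_numpy())
        stats_rows += _stats_rows([t_res], f"paired_t {a} vs {b}")
        try:
            table = chemo.joint_responsiveness_table(nets[a], nets[b])
            stats_rows += _stats_rows(
                [chemo.association_chi_square(table)], f"chi2 {a} vs {b}"
            )
        except ValueError as exc:  # zero margin in a small cohort
            logger.warning("chi-square skipped: %s", exc)
        long = net_df.merge(labels[["fiber_id", "label"]], on="fiber_id")
        long = long[long["label"].isin(["QC", "SC"])].rename(
            columns={"label": "fiber_type"}
        )
        anova = chemo.mixed_anova_fiber_pruritogen(long)
        stats_rows += _stats_rows(anova, "mixed_anova fiber_type x pruritogen")
        scheffe = chemo.scheffe_fiber_pruritogen(long)
        stats_rows += _stats_rows(scheffe, "scheffe cell means")
    return net_df, pd.DataFrame(tc_rows), stats_rows


def psychophysics_stage(in_dir, config: PipelineConfig):
    """Rating metrics, subject filters, RM-ANOVAs and area analyses."""
    in_dir = Path(in_dir)
    ratings = read_table(in_dir / "ratings.csv", "ratings")
    series = [
        psycho.RatingSeries(
            sid, stim, qual,
            grp.sort_values("time_min")["time_min"].to_numpy(),
            grp.sort_values("time_min")["rating"].to_numpy(),
        )
        for (sid, stim, qual), grp in ratings.groupby(
            ["subject_id", "stimulus", "quality"]
        )
    ]
    metrics = psycho.metrics_table(series)
    stats_rows: List[dict] = []
    peak_res = psycho.rmanova_gg(metrics, dv="peak", within=["stimulus", "quality"])
    stats_rows += _stats_rows(peak_res, "rmanova_gg peak")
    subset = psycho.filter_all_nonzero(metrics)
    if len(subset) >= 3:
        sub = metrics[metrics["subject_id"].isin(subset)]
        for dv in ("auc", "duration_min"):
            res = psycho.rmanova_gg(sub, dv=dv, within=["stimulus", "quality"])
            stats_rows += _stats_rows(res, f"rmanova_gg {dv} (all-nonzero subset)")
    areas_path = in_dir / "areas.csv"
    if areas_path.exists():
        areas = read_table(areas_path, "areas")
        for measure, results in psycho.area_analysis(areas).items():
            stats_rows += _stats_rows(results, f"rmanova_gg area {measure}")
    return metrics, stats_rows


def ish_stage(in_dir, config: PipelineConfig):
    """Co-expression summaries and the three-marker Venn table."""
    in_dir = Path(in_dir)
    table = read_table(in_dir / "puncta.csv", "puncta")
    records = [
        ish.NeuronPunctaRecord(
            species=r.species, donor_id=r.donor_id, section_id=r.section_id,
            neuron_id=r.neuron_id, marker=r.marker, puncta=int(r.puncta),
        )
        for r in table.itertuples()
    ]
    markers = sorted(table["marker"].unique())
    coexp_rows = []
    for a in markers:
        for b in markers:
            if a == b:
                continue
            s = ish.coexpression_summary(records, a, b, config.puncta_thresholds)
            coexp_rows.append(
                {
                    "marker_a": a,
                    "marker_b": b,
                    "mean_percent": s.mean_percent,
                    "sem_percent": s.sem_percent,
                    "double_positive": s.double_positive,
                    "a_positive": s.a_positive,
                    "aggregated_percent": s.aggregated_percent,
                }
            )
    venn_rows = []
    if len(markers) == 3:
        v = ish.venn_summary(records, markers, config.puncta_thresholds)
        for combo, count in v.region_counts.items():
            venn_rows.append(
                {
                    **{m: flag for m, flag in zip(markers, combo)},
                    "count": count,
                }
            )
    return pd.DataFrame(coexp_rows), pd.DataFrame(venn_rows)


def run_pipeline(config: PipelineConfig, in_dir=None) -> Dict[str, Path]:
    """Run every stage and write the report bundle.

    When ``in_dir`` is None the synthetic study defined by the config is
    generated first (simulate → analyze).  Outputs: classifications.csv,
    net_responses.csv, time_courses.csv, metrics.csv, coexpression.csv,
    venn.csv, stats.csv and run_log.json.  Any stage failure aborts with a
    stage-tagged error.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if in_dir is None:
        in_dir = out / "inputs"
        simulate_inputs(config, in_dir)
    in_dir = Path(in_dir)

    outputs: Dict[str, Path] = {}
    all_stats: List[dict] = []

    def _stage(name, fn):
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - re-raise with stage tag
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    labels = _stage("classify", lambda: classify_stage(in_dir, config))
    write_table(labels, out / "classifications.csv")
    outputs["classifications"] = out / "classifications.csv"

    net_df, tc_df, stats_rows = _stage("score", lambda: score_stage(in_dir, config, labels))
    write_table(net_df, out / "net_responses.csv")
    write_table(tc_df, out / "time_courses.csv")
    outputs["net_responses"] = out / "net_responses.csv"
    outputs["time_courses"] = out / "time_courses.csv"
    all_stats += stats_rows

    metrics, psy_stats = _stage("psychophysics", lambda: psychophysics_stage(in_dir, config))
    write_table(metrics, out / "metrics.csv")
    outputs["metrics"] = out / "metrics.csv"
    all_stats += psy_stats

    coexp, venn = _stage("ish", lambda: ish_stage(in_dir, config))
    write_table(coexp, out / "coexpression.csv")
    write_table(venn, out / "venn.csv")
    outputs["coexpression"] = out / "coexpression.csv"
    outputs["venn"] = out / "venn.csv"

    write_table(pd.DataFrame(all_stats), out / "stats.csv")
    outputs["stats"] = out / "stats.csv"

    import prurikit

    log = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "prurikit_version": prurikit.__version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
    }
    log_path = out / "run_log.json"
    log_path.write_text(json.dumps(log, indent=2))
    outputs["run_log"] = log_path
    return outputs
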