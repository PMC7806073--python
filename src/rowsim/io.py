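"""File formats, configuration and descriptive reporting.

Everything on disk is delimited UTF-8 text with a header row:

- trajectory files: ``time_s, theta_deg, delta_deg`` at a uniform rate;
- run manifests: one row per run (participant, group, day, run label,
  water condition, file path, seed);
- metrics tables: one row per run with the four outcome metrics and cycle
  counts — the tidy input any downstream mixed-model analysis needs;
- coefficient tables: ``alpha_deg, c_d, c_l``.

Configuration is a single YAML file mirroring every printed constant of
the study (densities, stroke period and spans, resample count, cadence
band, exclusion counts, run durations); nothing is hard-coded in the
pipeline once a config is loaded.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .evaluate import MetricConfig, RunMetrics, evaluate_run, reference_cycle
from .hydro import CoefficientTable, OarGeometry, condition_by_label
from .reference import ReferenceSpec, Trajectory

__all__ = [
    "TrajectoryFormatError",
    "read_trajectory",
    "write_trajectory",
    "read_coefficient_table",
    "write_coefficient_table",
    "write_manifest",
    "read_manifest",
    "PipelineConfig",
    "evaluate_manifest",
    "report_summary",
    "kr_chart_series",
]

logger = logging.getLogger("rowsim")

_TRAJ_COLUMNS = ("time_s", "theta_deg", "delta_deg")
_UNIFORMITY_TOL_S = 1e-6


class TrajectoryFormatError(ValueError):
    """A trajectory file violates the on-disk contract."""


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as CSV (time_s, theta_deg, delta_deg)."""
    df = pd.DataFrame({"time_s": traj.times, "theta_deg": traj.theta,
                       "delta_deg": traj.delta})
    df.to_csv(path, index=False, float_format="%.10g")


def read_trajectory(path: str | Path) -> Trajectory:
    """Read and validate a trajectory CSV.

    The time column must be strictly increasing and uniformly sampled to
    within 1e-6 s; violations raise TrajectoryFormatError naming the
    offending row.
    """
    df = pd.read_csv(path)
    missing = [c for c in _TRAJ_COLUMNS if c not in df.columns]
    if missing:
        raise TrajectoryFormatError(f"{path}: missing columns {missing}")
    t = df["time_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise TrajectoryFormatError(f"{path}: need at least 2 samples")
    dt = np.diff(t)
    bad = np.where(dt <= 0)[0]
    if bad.size:
        # +3: 1-based file rows, header line, and dt[i] implicating row i+1
        raise TrajectoryFormatError(
            f"{path}: non-monotone time at row {bad[0] + 3}")
    step = float(np.median(dt))
    off = np.where(np.abs(dt - step) > _UNIFORMITY_TOL_S)[0]
    if off.size:
        raise TrajectoryFormatError(
            f"{path}: non-uniform sampling at row {off[0] + 3} "
            f"(step {dt[off[0]]:.6g} s vs {step:.6g} s)")
    return Trajectory(times=t, theta=df["theta_deg"].to_numpy(dtype=float),
                      delta=df["delta_deg"].to_numpy(dtype=float),
                      sample_rate=1.0 / step)


def write_coefficient_table(table: CoefficientTable, path: str | Path) -> None:
    pd.DataFrame({"alpha_deg": table.alpha_grid, "c_d": table.drag_coeffs,
                  "c_l": table.lift_coeffs}).to_csv(path, index=False)


def read_coefficient_table(path: str | Path) -> CoefficientTable:
    df = pd.read_csv(path)
    for c in ("alpha_deg", "c_d", "c_l"):
        if c not in df.columns:
            raise TrajectoryFormatError(f"{path}: missing column {c!r}")
    return CoefficientTable(alpha_grid=df["alpha_deg"].to_numpy(float),
                            drag_coeffs=df["c_d"].to_numpy(float),
                            lift_coeffs=df["c_l"].to_numpy(float))


_MANIFEST_COLUMNS = ("participant", "group", "day", "run_label", "condition",
                     "file_path", "seed")


def write_manifest(records: list[dict], path: str | Path) -> None:
    """Write a run manifest (one row per trajectory file)."""
    df = pd.DataFrame(records, columns=list(_MANIFEST_COLUMNS))
    df.to_csv(path, index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in _MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise TrajectoryFormatError(f"{path}: manifest missing columns {missing}")
    for lbl in df["condition"].unique():
        condition_by_label(str(lbl))  # raises KeyError on unknown labels
    return df


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable constants of the pipeline in one validated object."""

    geometry: OarGeometry = field(default_factory=OarGeometry)
    reference: ReferenceSpec = field(default_factory=ReferenceSpec)
    metrics: MetricConfig = field(default_factory=MetricConfig)
    coefficient_table_path: str | None = None
    sample_rate: float = 100.0
    test_duration_s: float = 120.0
    nofeedback_duration_s: float = 60.0
    master_seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        if "geometry" in raw:
            kwargs["geometry"] = OarGeometry(**raw["geometry"])
        if "reference" in raw:
            ref = dict(raw["reference"])
            if "phase_fractions" in ref:
                ref["phase_fractions"] = tuple(ref["phase_fractions"])
            kwargs["reference"] = ReferenceSpec(**ref)
        if "metrics" in raw:
            met = dict(raw["metrics"])
            if "cadence_band_spm" in met:
                met["cadence_band_spm"] = tuple(met["cadence_band_spm"])
            kwargs["metrics"] = MetricConfig(**met)
        for key in ("coefficient_table_path", "sample_rate", "test_duration_s",
                    "nofeedback_duration_s", "master_seed", "log_level"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        raw = {
            "geometry": asdict(self.geometry),
            "reference": {**asdict(self.reference),
                          "phase_fractions": list(self.reference.phase_fractions)},
            "metrics": {**asdict(self.metrics),
                        "cadence_band_spm": list(self.metrics.cadence_band_spm)},
            "coefficient_table_path": self.coefficient_table_path,
            "sample_rate": self.sample_rate,
            "test_duration_s": self.test_duration_s,
            "nofeedback_duration_s": self.nofeedback_duration_s,
            "master_seed": self.master_seed,
            "log_level": self.log_level,
        }
        Path(path).write_text(yaml.safe_dump(raw, sort_keys=False))


_METRIC_COLS = ("eps_s", "eps_v", "nu_s", "nu_v")


def evaluate_manifest(manifest: pd.DataFrame, base_dir: str | Path = ".",
                      spec: ReferenceSpec | None = None,
                      config: MetricConfig | None = None) -> pd.DataFrame:
    """Evaluate every run listed in a manifest into a tidy metrics table.

    Every manifest row appears exactly once in the output; runs whose
    metrics are undefined carry NaN values rather than being dropped.
    """
    config = config or MetricConfig()
    ref = reference_cycle(spec, config)
    rows = []
    for rec in manifest.itertuples(index=False):
        traj = read_trajectory(Path(base_dir) / rec.file_path)
        metrics: RunMetrics = evaluate_run(traj, ref, config)
        logger.info("run %s/%s: %d cycles, %d valid",
                    rec.participant, rec.run_label,
                    metrics.n_cycles_total, metrics.n_cycles_valid)
        rows.append({"participant": rec.participant, "group": rec.group,
                     "day": rec.day, "run_label": rec.run_label,
                     "condition": rec.condition, **metrics.as_dict()})
    return pd.DataFrame(rows)


def report_summary(metrics_table: pd.DataFrame,
                   grouping: tuple[str, ...] = ("group", "run_label")) -> pd.DataFrame:
    """Descriptive per-cell summaries of the four outcome metrics.

    Returns mean, median, lower and upper quartile and count for each
    metric within each grouping cell (default: per group per test) —
    the descriptive content of a group-comparison figure, without
    inferential statistics.
    """
    if metrics_table.empty:
        raise ValueError("metrics table is empty")
    for key in grouping:
        if key not in metrics_table.columns:
            raise ValueError(f"unknown grouping key {key!r}")
    aggs = ["mean", "median", lambda s: s.quantile(0.25),
            lambda s: s.quantile(0.75), "count"]
    out = metrics_table.groupby(list(grouping))[list(_METRIC_COLS)].agg(aggs)
    out.columns = [f"{m}_{s}" for m, s in zip(
        out.columns.get_level_values(0),
        ["mean", "median", "q25", "q75", "n"] * len(_METRIC_COLS))]
    return out.reset_index()


def kr_chart_series(metrics_table: pd.DataFrame, participant: str) -> pd.DataFrame:
    """Knowledge-of-results chart series for one participant.

    Mean spatial and velocity error per test run, in protocol order —
    what the participant saw on the 2D line chart after each test.
    """
    sub = metrics_table[metrics_table["participant"] == participant]
    if sub.empty:
        raise ValueError(f"no runs for participant {participant!r}")
    tests = sub[~sub["run_label"].str.startswith("TR")
                | sub["run_label"].str.startswith("TRS")]
    return tests[["run_label", "day", "eps_s", "eps_v"]].reset_index(drop=True)


def plot_kr_chart(series: pd.DataFrame, path: str | Path) -> None:
    """Render the knowledge-of-results line chart to a file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 3.5))
    x = np.arange(len(series))
    ax.plot(x, series["eps_s"], "o-", label="spatial error (deg)")
    ax.plot(x, series["eps_v"], "s-", label="velocity error (deg/s)")
    ax.set_xticks(x, series["run_label"], rotation=45, ha="right")
    ax.set_ylabel("mean error")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
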