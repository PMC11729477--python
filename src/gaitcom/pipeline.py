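"""End-to-end orchestration: simulate -> condition -> detect -> normalize
-> agreement + SPM, with a machine-readable report.

Three acceleration streams are compared per subject:

* ``IMU``  — the sensor channel, low-pass filtered (2nd order, 12 Hz) and
  gravity-corrected;
* ``ML5``  — the marker on the sensor, filtered (4th order, 12 Hz) and
  twice differentiated;
* ``CoM``  — the 13-segment whole-body CoM from all markers, filtered and
  twice differentiated.

Cycles are delimited by same-foot heel strikes: camera streams use the
heel-marker events, the IMU stream uses its own wavelet-detected initial
contacts paired against the camera events (clock offset removed).  Each
interior cycle is resampled to 101 nodes; the per-subject condition curve
is the ensemble average over cycles.  Agreement statistics pool physical
accelerations; SPM runs on the [-1, 1]-normalized curves, per direction.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .agreement import bland_altman, pearson, pool_points
from .body_model import BodyModel, MarkerFrameSeries, default_body_model, whole_body_com
from .cycles import (CONDITIONS, DIRECTIONS, N_NODES, NormalizedCycleSet,
                     ensemble_average, segment_cycles, time_normalize)
from .errors import ConfigurationError, GaitcomError
from .gait_events import EventSeries, detect_hs_camera, detect_hs_imu, match_events
from .signal_processing import (FilterSpec, UniformSeries, butterworth_zero_lag,
                                finite_difference, gravity_correct)
from .synthetic import GaitSimConfig, SyntheticTrial, generate_cohort

__all__ = ["RunConfig", "run_pipeline", "process_trial", "PAIRS"]

PAIRS = (("IMU", "CoM"), ("IMU", "ML5"), ("ML5", "CoM"))


@dataclass
class RunConfig:
    """Validated pipeline settings; defaults are the study's printed values."""

    sim: GaitSimConfig = field(default_factory=GaitSimConfig)
    marker_filter_order: int = 4        # effective, forward-backward
    marker_filter_cutoff: float = 12.0  # Hz
    imu_filter_order: int = 2
    imu_filter_cutoff: float = 12.0
    gravity: float = 9.81
    foot: str = "right"                 # tracked foot for cycle definition
    event_tolerance: float = 0.10       # s, cross-system pairing window
    n_nodes: int = N_NODES
    alpha: float = 0.05
    alpha_posthoc: float | None = None  # None -> alpha / 3 pairwise comparisons
    n_perm: int = 0                     # >0 adds a permutation cross-check to the report
    shared_events: bool = False         # use camera events for every stream
    seed: int | None = None             # overrides sim.seed when given
    out_dir: str | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.foot not in ("left", "right"):
            raise ConfigurationError("foot must be 'left' or 'right'")
        if self.n_nodes != N_NODES:
            raise ConfigurationError(f"n_nodes must be {N_NODES}")
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must be in (0, 1)")
        if self.event_tolerance <= 0:
            raise ConfigurationError("event_tolerance must be positive")
        if self.seed is not None:
            self.sim = dataclasses.replace(self.sim, seed=int(self.seed))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = GaitSimConfig(**{
            k: tuple(v) if k == "sensor_offset" else v
            for k, v in (raw.pop("sim", {}) or {}).items()
        })
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(sim=sim, **raw)

    def echo(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"]["sensor_offset"] = list(d["sim"]["sensor_offset"])
        return d


def _filter_markers(markers: MarkerFrameSeries, spec: FilterSpec) -> MarkerFrameSeries:
    filtered = {
        name: butterworth_zero_lag(
            UniformSeries(markers.rate, pos, unit="m", t0=markers.t0), spec
        ).values
        for name, pos in markers.positions.items()
    }
    return MarkerFrameSeries(rate=markers.rate, positions=filtered, t0=markers.t0)


def process_trial(
    trial: SyntheticTrial,
    config: RunConfig,
    model: BodyModel | None = None,
):
    """One subject: conditioned streams -> events -> 101-node condition curves.

    Returns ``(curves, info)`` where ``curves`` maps condition name to a
    (101, 3) ensemble-average acceleration curve in m/s^2 and ``info``
    carries events, the estimated clock offset and warnings.
    """
    model = model or default_body_model()
    info: dict = {"warnings": []}

    marker_spec = FilterSpec(config.marker_filter_order, config.marker_filter_cutoff,
                             trial.markers.rate)
    imu_spec = FilterSpec(config.imu_filter_order, config.imu_filter_cutoff,
                          trial.imu.rate)

    markers_f = _filter_markers(trial.markers, marker_spec)
    com_acc = finite_difference(
        UniformSeries(markers_f.rate, whole_body_com(model, markers_f).com, unit="m"),
        deriv_order=2,
    )
    ml5_acc = finite_difference(
        UniformSeries(markers_f.rate, markers_f.positions["ML5"], unit="m"),
        deriv_order=2,
    )
    imu_f = butterworth_zero_lag(trial.imu, imu_spec)
    imu_acc = gravity_correct(imu_f, g=config.gravity)

    heel = f"{'L' if config.foot == 'left' else 'R'}_HEEL"
    heel_z = UniformSeries(markers_f.rate, markers_f.positions[heel][:, 2], unit="m")
    cam_events = detect_hs_camera(heel_height=heel_z)
    cam_events.foot = config.foot
    info["camera_events"] = cam_events

    if config.shared_events:
        imu_events = EventSeries(cam_events.times.copy(), source="imu", foot=config.foot)
        info["offset"] = 0.0
    else:
        ic = detect_hs_imu(UniformSeries(imu_acc.rate, imu_acc.values[:, 2], unit="m/s^2"))
        match = match_events(cam_events, ic, tolerance=config.event_tolerance)
        info["offset"] = match.offset
        if match.unpaired_camera:
            info["warnings"].append(
                f"{trial.subject_id}: {len(match.unpaired_camera)} camera event(s) unpaired"
            )
        # paired IMU initial contacts of the tracked foot, offset-corrected
        times = np.sort([ic.times[j] - match.offset for _, j in match.pairs])
        imu_events = EventSeries(times, source="imu", foot=config.foot)
    info["imu_events"] = imu_events

    curves: dict[str, np.ndarray] = {}
    for cond, series, events in (
        ("IMU", imu_acc, imu_events),
        ("ML5", ml5_acc, cam_events),
        ("CoM", com_acc, cam_events),
    ):
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            cycles = segment_cycles(series, events)
            nodes = [time_normalize(c, config.n_nodes) for c in cycles]
            mean, _sd = ensemble_average(nodes)
        info["warnings"].extend(f"{trial.subject_id}/{cond}: {w.message}" for w in caught)
        curves[cond] = mean
    return curves, info


def _agreement_block(cycleset: NormalizedCycleSet) -> dict:
    out = {}
    for pair in PAIRS:
        key = f"{pair[0]}_vs_{pair[1]}"
        block = {}
        pooled = pool_points(cycleset, pair)
        r, p = pearson(pooled)
        ba = bland_altman(pooled)
        block.update(r=r, p=p, n=pooled.n, bias=ba.bias, sd=ba.sd,
                     loa_lower=ba.loa_lower, loa_upper=ba.loa_upper)
        per_dir = {}
        for d in cycleset.directions:
            pd_pool = pool_points(cycleset, pair, direction=d)
            rd, pdv = pearson(pd_pool)
            bad = bland_altman(pd_pool)
            per_dir[d] = dict(r=rd, p=pdv, n=pd_pool.n, bias=bad.bias, sd=bad.sd,
                              loa_lower=bad.loa_lower, loa_upper=bad.loa_upper)
        block["per_direction"] = per_dir
        out[key] = block
    return out


def _spm_result_dict(res) -> dict:
    return {
        "stat": res.stat,
        "dof": list(res.dof),
        "fwhm": res.fwhm if np.isfinite(res.fwhm) else None,
        "resels": res.resels,
        "threshold": res.threshold,
        "alpha": res.alpha,
        "degenerate": res.degenerate,
        "field": np.asarray(res.field, dtype=float).tolist(),
        "clusters": [
            {"start_pct": c.start_pct, "end_pct": c.end_pct, "peak": c.peak, "p": c.p}
            for c in res.clusters
        ],
    }


def _spm_block(cycleset: NormalizedCycleSet, config: RunConfig, report_warnings: list) -> dict:
    from .spm import SpmDesign, permutation_oracle, posthoc_paired_t, spm_anova

    out = {}
    for d_i, direction in enumerate(cycleset.directions):
        design = SpmDesign(
            cycleset.data[:, :, :, d_i],
            condition_names=cycleset.conditions,
            alpha=config.alpha,
            alpha_posthoc=config.alpha_posthoc,
        )
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            omnibus = spm_anova(design)
            posthoc = {
                f"{a}_vs_{b}": _spm_result_dict(posthoc_paired_t(design, (a, b)))
                for a, b in PAIRS
            }
        report_warnings.extend(f"SPM/{direction}: {w.message}" for w in caught)
        block = {"anova": _spm_result_dict(omnibus), "posthoc": posthoc}
        if config.n_perm > 0:
            perm = permutation_oracle(design, n_perm=config.n_perm,
                                      seed=design.data.shape[0] + d_i, stat="F")
            block["permutation_check"] = {
                "threshold": perm.threshold, "n_perm": perm.n_perm,
                "rft_threshold": omnibus.threshold,
            }
        out[direction] = block
    return out


def run_pipeline(config: RunConfig, cohort: list[SyntheticTrial] | None = None) -> dict:
    """Execute the full chain on a (possibly pre-generated) cohort.

    Returns the run report; when ``config.out_dir`` is set, the report, the
    long-format cycle table and the per-subject event lists are written
    there as well.
    """
    cohort = cohort if cohort is not None else generate_cohort(config.sim)
    report_warnings: list[str] = []

    all_curves: list[np.ndarray] = []
    subjects: list[str] = []
    events_out: list[EventSeries] = []
    for trial in cohort:
        try:
            curves, info = process_trial(trial, config)
        except GaitcomError as exc:
            raise type(exc)(f"subject {trial.subject_id}: {exc}") from exc
        report_warnings.extend(info["warnings"])
        events_out.extend([info["camera_events"], info["imu_events"]])
        all_curves.append(np.stack([curves[c] for c in CONDITIONS]))
        subjects.append(trial.subject_id)

    cycleset = NormalizedCycleSet(np.stack(all_curves), tuple(subjects))
    normalized = cycleset.amplitude_normalized()

    report: dict = {
        "software": {"name": "gaitcom", "version": __version__},
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "seed": config.sim.seed,
        "config": config.echo(),
        "n_subjects": len(subjects),
        "pooled_n": len(subjects) * N_NODES * len(DIRECTIONS),
        "agreement": _agreement_block(cycleset),
    }
    if len(subjects) >= 3:
        report["spm"] = _spm_block(normalized, config, report_warnings)
    else:
        # with < 3 subjects the post-hoc t field has <= 1 denominator dof
        # and RFT inference is ill-posed
        report_warnings.append("SPM skipped: fewer than 3 subjects")
        report["spm"] = None
    report["warnings"] = report_warnings

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=2))
        cycleset.to_long().to_csv(out / "cycles_physical.csv", index=False)
        normalized.to_long().to_csv(out / "cycles_normalized.csv", index=False)
        from .io import write_events_csv

        write_events_csv(events_out, out / "events.csv")
    return report
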