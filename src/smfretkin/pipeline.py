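"""One-command orchestration: simulate/load -> E_FRET -> HMM -> rates -> energies.

A :class:`RunConfig` mirrors the module defaults with one block per stage;
unknown keys anywhere in the config are rejected by name.  Every stage
writes its tabular output under the run directory and the final manifest
records each file with a SHA-256 digest, the full parameter echo, the
package version, and the seed — identical config + seed reproduces
identical digests for all deterministic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .hmm import fit_baum_welch, map_states_to_levels, select_k, viterbi_all
from .kinetics import (
    build_rate_table,
    build_tdp,
    build_todp,
    extract_dwells,
    self_calibrate_rates,
)
from .preprocess import (
    EfretSeries,
    classify_response,
    compute_efret,
    detect_bleach,
)
from .synth import KineticScheme, SimConfig, default_scheme, simulate_experiment
from .thermo import ArrheniusParams, LandscapeError, build_landscape
from .trace_io import read_traces, write_traces

__all__ = [
    "RunConfig",
    "ConfigError",
    "PipelineError",
    "run_pipeline",
    "recover_rates",
]

#: canonical ordering of the conformations along the reaction coordinate
_COORDINATE = ["E", "N", "F", "C"]


class ConfigError(ValueError):
    pass


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class SimulateBlock:
    scheme: str = "Mg30"  # shipped name or path to a YAML scheme file
    pre_scheme: str | None = None
    n_traces: int = 100
    n_frames: int = 1000
    frame_period: float = 0.05
    injection_frame: int | None = None
    responder_fraction: float = 1.0
    delay_rate: float | None = None
    donor_bleach_rate: float = 0.0
    acceptor_bleach_rate: float = 0.0
    total_intensity_mean: float = 500.0
    total_intensity_sd: float = 50.0
    channel_noise_sd: float = 10.0
    substeps_per_frame: int = 10


@dataclass
class InputBlock:
    traces: str | None = None
    format: str = "csv"


@dataclass
class PreprocessBlock:
    denom_floor_frac: float = 0.10
    detect_bleach: bool = True
    baseline_fraction: float = 0.25
    persistence: int = 10
    pre_frames: int = 40
    post_frames: int = 40
    min_shift: float = 0.10


@dataclass
class HmmBlock:
    k: int | str = "auto"
    k_min: int = 2
    k_max: int = 4
    tol: float = 1e-6
    max_iter: int = 500
    label_tolerance: float = 0.08


@dataclass
class KineticsBlock:
    min_frames: int = 2
    min_molecules: int = 20
    min_dwells: int = 10
    dead_frames: int = 2
    correct_discretization: bool = True
    calibrate: bool = True
    calibration_rounds: int = 2
    bin_width: float = 0.02
    bootstrap_n: int = 100


@dataclass
class ThermoBlock:
    state_order: list[str] | None = None
    A: float = 1e3
    R: float = 8.31
    T_K: float = 297.0
    R0_nm: float = 5.4


@dataclass
class OutputBlock:
    write_traces: bool = True
    write_efret: bool = True


@dataclass
class RunConfig:
    seed: int = 0
    condition: str = ""
    simulate: SimulateBlock | None = field(default_factory=SimulateBlock)
    input: InputBlock | None = None
    preprocess: PreprocessBlock = field(default_factory=PreprocessBlock)
    hmm: HmmBlock = field(default_factory=HmmBlock)
    kinetics: KineticsBlock = field(default_factory=KineticsBlock)
    thermo: ThermoBlock = field(default_factory=ThermoBlock)
    output: OutputBlock = field(default_factory=OutputBlock)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return _strict(cls, d, "config")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


_BLOCKS = {
    "simulate": SimulateBlock,
    "input": InputBlock,
    "preprocess": PreprocessBlock,
    "hmm": HmmBlock,
    "kinetics": KineticsBlock,
    "thermo": ThermoBlock,
    "output": OutputBlock,
}


def _strict(cls, d: dict, where: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = sorted(set(d) - names)
    if unknown:
        raise ConfigError(f"unknown key(s) {unknown} in {where}")
    kwargs = {}
    for key, value in d.items():
        sub = _BLOCKS.get(key)
        if sub is not None and isinstance(value, dict):
            kwargs[key] = _strict(sub, value, where=key)
        else:
            kwargs[key] = value
    return cls(**kwargs)


def _resolve_scheme(name: str) -> KineticScheme:
    p = Path(name)
    if p.suffix in (".yml", ".yaml") and p.exists():
        with open(p) as fh:
            return KineticScheme.from_dict(yaml.safe_load(fh))
    return default_scheme(name)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _phase_segments(e: EfretSeries, post_only: bool) -> EfretSeries:
    if not post_only or e.injection_frame is None:
        return e
    segs = [(max(s, e.injection_frame), t) for s, t in e.analysis_segments
            if t > e.injection_frame]
    return EfretSeries(
        trace_id=e.trace_id, E=e.E, valid=e.valid, frame_period=e.frame_period,
        injection_frame=e.injection_frame, analysis_segments=segs,
    )


def recover_rates(
    scheme: str | KineticScheme,
    n_traces: int,
    n_frames: int,
    seed: int,
    k: int = 3,
    min_frames: int = 2,
    min_molecules: int = 20,
    calibrate: bool = True,
    bootstrap_n: int = 0,
    fit_chunk: int | None = None,
):
    """Simulate a condition and run the full in-memory analysis chain.

    Returns ``(fit, labels, rates, paths)``: the fitted HMM, its level
    labels, the (optionally self-calibrated) rate table, and the decoded
    paths.  ``fit_chunk`` fits the model on fixed-length sub-segments while
    decoding the full traces, which keeps the EM batch well-shaped for very
    long recordings.
    """
    if isinstance(scheme, str):
        scheme = _resolve_scheme(scheme)
    sim = SimConfig(pre_scheme=scheme, n_traces=n_traces, n_frames=n_frames,
                    seed=seed)
    ts, _ = simulate_experiment(sim)
    series = [compute_efret(t) for t in ts]

    if fit_chunk:
        fit_input = []
        for e in series:
            for lo in range(0, e.n_frames, fit_chunk):
                hi = min(lo + fit_chunk, e.n_frames)
                fit_input.append(
                    EfretSeries(trace_id=f"{e.trace_id}:{lo}", E=e.E[lo:hi],
                                valid=e.valid[lo:hi], frame_period=e.frame_period)
                )
    else:
        fit_input = series
    fit = fit_baum_welch(fit_input, k)
    labels = map_states_to_levels(fit.model)
    paths = [p.labeled(labels) for p in viterbi_all(fit.model, series)]

    dwells, transitions = [], []
    for p in paths:
        d, t = extract_dwells(p, min_frames=min_frames)
        dwells.extend(d)
        transitions.extend(t)
    rates = build_rate_table(
        dwells, transitions, frame_period=sim.frame_period,
        min_molecules=min_molecules, dead_frames=min_frames,
        bootstrap_n=bootstrap_n, seed=seed,
    )
    if calibrate and rates.included():
        seg_lens = [hi - lo for p in paths for lo, hi in p.segments]
        rates = self_calibrate_rates(
            rates, fit.model, labels, seg_lens,
            min_frames=min_frames, dead_frames=min_frames, seed=seed + 1,
        )
    return fit, labels, rates, paths


def run_pipeline(cfg: RunConfig, out_dir: str | Path) -> dict:
    """Run every stage and return (and write) the manifest.

    The manifest lists per-stage counts in/out, every output file with its
    digest, the echoed parameters, the package version, and the seed.  A
    stage failure writes a manifest carrying ``failed_stage`` before the
    :class:`PipelineError` propagates; partial outputs are retained.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "parameters": dataclasses.asdict(cfg),
        "stages": {},
        "files": {},
    }

    def record(name: str, **info) -> None:
        manifest["stages"][name] = info

    def add_file(path: Path) -> None:
        manifest["files"][path.name] = _sha256(path)

    def finish(failed: str | None = None) -> dict:
        if failed:
            manifest["failed_stage"] = failed
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        return manifest

    stage = "input"
    try:
        if cfg.input is not None and cfg.input.traces:
            ts = read_traces(cfg.input.traces, format=cfg.input.format)
            truths = None
        else:
            sim = cfg.simulate or SimulateBlock()
            post = None
            pre = _resolve_scheme(sim.scheme)
            if sim.injection_frame is not None:
                post = pre
                pre = _resolve_scheme(sim.pre_scheme or "Native")
            sc = SimConfig(
                pre_scheme=pre,
                post_scheme=post,
                injection_frame=sim.injection_frame,
                n_traces=sim.n_traces,
                n_frames=sim.n_frames,
                frame_period=sim.frame_period,
                substeps_per_frame=sim.substeps_per_frame,
                total_intensity_mean=sim.total_intensity_mean,
                total_intensity_sd=sim.total_intensity_sd,
                channel_noise_sd=sim.channel_noise_sd,
                donor_bleach_rate=sim.donor_bleach_rate,
                acceptor_bleach_rate=sim.acceptor_bleach_rate,
                responder_fraction=sim.responder_fraction,
                delay_rate=sim.delay_rate,
                seed=cfg.seed,
            )
            ts, truths = simulate_experiment(sc)
            if cfg.output.write_traces:
                write_traces(ts, out / "traces.csv")
                add_file(out / "traces.csv")
                add_file(out / "traces.meta.csv")
                pd.DataFrame(
                    {
                        "trace_id": [t.trace_id for t in truths],
                        "responder": [t.responder for t in truths],
                        "delay_s": [t.delay_s for t in truths],
                        "donor_bleach_frame": [t.donor_bleach_frame for t in truths],
                        "acceptor_bleach_frame": [t.acceptor_bleach_frame for t in truths],
                    }
                ).to_csv(out / "ground_truth.csv", index=False)
                add_file(out / "ground_truth.csv")
        record(stage, n_traces=len(ts))

        stage = "preprocess"
        series = []
        for t in ts:
            bleach = detect_bleach(
                t, cfg.preprocess.baseline_fraction, cfg.preprocess.persistence
            ) if cfg.preprocess.detect_bleach else None
            series.append(compute_efret(t, bleach, cfg.preprocess.denom_floor_frac))
        if cfg.output.write_efret:
            rows = []
            for e in series:
                rows.append(
                    pd.DataFrame(
                        {
                            "trace_id": e.trace_id,
                            "frame": np.arange(e.n_frames),
                            "time_s": np.arange(e.n_frames) * e.frame_period,
                            "E": e.E,
                            "valid": e.valid,
                        }
                    )
                )
            pd.concat(rows).to_csv(out / "efret.csv", index=False)
            add_file(out / "efret.csv")
        record(stage, n_series=len(series),
               n_valid_frames=int(sum(e.n_valid for e in series)))

        stage = "idealize"
        has_injection = any(e.injection_frame is not None for e in series)
        fit_series = [_phase_segments(e, post_only=has_injection) for e in series]
        usable = [e for e in fit_series if any(
            hi - lo > 0 for lo, hi in e.analysis_segments)]
        if cfg.hmm.k == "auto":
            k = select_k(usable, range(cfg.hmm.k_min, cfg.hmm.k_max + 1),
                         tol=cfg.hmm.tol, max_iter=cfg.hmm.max_iter)
        else:
            k = int(cfg.hmm.k)
        fit = fit_baum_welch(usable, k, tol=cfg.hmm.tol, max_iter=cfg.hmm.max_iter)
        labels = map_states_to_levels(fit.model, tolerance=cfg.hmm.label_tolerance)
        paths = [p.labeled(labels) for p in viterbi_all(fit.model, fit_series)]
        with open(out / "model.yaml", "w") as fh:
            yaml.safe_dump(
                {
                    "k": k,
                    "means": [float(m) for m in fit.model.means],
                    "variances": [float(v) for v in fit.model.variances],
                    "transmat": [[float(x) for x in row] for row in fit.model.transmat],
                    "startprob": [float(x) for x in fit.model.startprob],
                    "state_labels": {int(i): l for i, l in labels.items()},
                    "log_likelihood": float(fit.log_likelihood),
                    "n_iter": fit.n_iter,
                    "converged": fit.converged,
                },
                fh,
            )
        add_file(out / "model.yaml")
        pd.concat(
            [
                pd.DataFrame(
                    {
                        "trace_id": p.trace_id,
                        "frame": np.arange(p.n_frames),
                        "state_index": p.states,
                        "state_label": [
                            labels.get(int(s), "") if s >= 0 else "" for s in p.states
                        ],
                    }
                )
                for p in paths
            ]
        ).to_csv(out / "path.csv", index=False)
        add_file(out / "path.csv")
        record(stage, k=k, log_likelihood=float(fit.log_likelihood),
               n_iter=fit.n_iter, converged=fit.converged)

        if has_injection:
            stage = "classify"
            calls = []
            for e in series:
                calls.append(
                    classify_response(
                        e,
                        pre_frames=cfg.preprocess.pre_frames,
                        post_frames=cfg.preprocess.post_frames,
                        min_shift=cfg.preprocess.min_shift,
                    )
                )
            pd.DataFrame(
                {
                    "trace_id": [c.trace_id for c in calls],
                    "call": [c.call for c in calls],
                    "pre_level": [c.pre_level for c in calls],
                    "post_level": [c.post_level for c in calls],
                    "delay_s": [c.delay_s for c in calls],
                }
            ).to_csv(out / "response_calls.csv", index=False)
            add_file(out / "response_calls.csv")
            tallies = {call: sum(1 for c in calls if c.call == call)
                       for call in ("fold", "extend", "dynamic", "static", "rejected")}
            record(stage, **tallies)

        stage = "kinetics"
        means_by_label = {
            lab: float(fit.model.means[i]) for i, lab in labels.items()
        }
        dwells, transitions = [], []
        for p in paths:
            d, tr = extract_dwells(p, min_frames=cfg.kinetics.min_frames,
                                   state_means=means_by_label)
            dwells.extend(d)
            transitions.extend(tr)
        rates = build_rate_table(
            dwells,
            transitions,
            frame_period=series[0].frame_period if series else 0.05,
            min_molecules=cfg.kinetics.min_molecules,
            min_dwells=cfg.kinetics.min_dwells,
            dead_frames=cfg.kinetics.dead_frames,
            correct_discretization=cfg.kinetics.correct_discretization,
            bootstrap_n=cfg.kinetics.bootstrap_n,
            seed=cfg.seed,
        )
        if cfg.kinetics.calibrate and rates.included():
            seg_lens = [hi - lo for p in paths for lo, hi in p.segments]
            rates = self_calibrate_rates(
                rates,
                fit.model,
                labels,
                seg_lens,
                min_frames=cfg.kinetics.min_frames,
                dead_frames=cfg.kinetics.dead_frames,
                correct_discretization=cfg.kinetics.correct_discretization,
                min_dwells=cfg.kinetics.min_dwells,
                n_rounds=cfg.kinetics.calibration_rounds,
                seed=cfg.seed + 1,
            )
        pd.DataFrame(
            {
                "trace_id": [d.trace_id for d in dwells],
                "state": [d.state_label for d in dwells],
                "start_frame": [d.start_frame for d in dwells],
                "end_frame": [d.end_frame for d in dwells],
                "duration_s": [d.duration for d in dwells],
                "prev_state": [d.prev_state for d in dwells],
                "next_state": [d.next_state for d in dwells],
                "censored_left": [d.censored_left for d in dwells],
                "censored_right": [d.censored_right for d in dwells],
            }
        ).to_csv(out / "dwells.csv", index=False)
        add_file(out / "dwells.csv")
        (out / "rates.json").write_text(json.dumps(rates.to_dict(), indent=2))
        add_file(out / "rates.json")
        tdp = build_tdp(transitions, bin_width=cfg.kinetics.bin_width)
        todp = build_todp(transitions, n_molecules_total=len(ts),
                          bin_width=cfg.kinetics.bin_width)
        np.savetxt(out / "tdp.csv", tdp.matrix, delimiter=",")
        np.savetxt(out / "todp.csv", todp.matrix, delimiter=",")
        add_file(out / "tdp.csv")
        add_file(out / "todp.csv")
        record(stage, n_dwells=len(dwells), n_transitions=len(transitions),
               n_rates_included=len(rates.included()))

        stage = "energy"
        params = ArrheniusParams(A=cfg.thermo.A, R=cfg.thermo.R, T=cfg.thermo.T_K)
        order = cfg.thermo.state_order
        auto_order = order is None
        if auto_order:
            present = {s for pair in rates.included() for s in pair}
            order = [s for s in _COORDINATE if s in present]
        try:
            ls = build_landscape(rates, order, params, condition=cfg.condition)
        except LandscapeError:
            if not auto_order:
                raise
            ls = None
            record(stage, skipped="adjacent rates missing for automatic coordinate")
        if ls is not None:
            rows = []
            for i, s in enumerate(ls.states):
                nxt = ls.states[i + 1] if i + 1 < len(ls.states) else None
                rows.append(
                    {
                        "state": s,
                        "well_J_mol": ls.wells[s],
                        "barrier_to_next_J_mol": (
                            ls.barriers[(s, nxt)] if nxt else ""
                        ),
                    }
                )
            pd.DataFrame(rows).to_csv(out / "landscape.csv", index=False)
            add_file(out / "landscape.csv")
            record(stage, states=ls.states,
                   wells={s: float(w) for s, w in ls.wells.items()})
        return finish()
    except Exception as exc:
        finish(failed=stage)
        raise PipelineError(stage, exc) from exc
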