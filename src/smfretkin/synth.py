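"""Synthetic smFRET trace generation from explicit kinetic schemes.

The conformational dynamics of a surface-tethered molecule are modeled as a
continuous-time Markov chain (CTMC) over a small set of states, each with a
characteristic mean FRET efficiency.  Exact stochastic (Gillespie) sampling
of the chain yields a piecewise-constant state path; the camera then
integrates that path into frames: the noiseless per-frame efficiency is the
exact time-weighted average of the state means over the frame, one Gaussian
state-level jitter (occupancy-weighted ``sd_E``) is added per frame, and the
two channel intensities are rendered as ``acceptor = E * I_T + noise`` and
``donor = (1 - E) * I_T + noise`` with a per-trace total intensity ``I_T``.

Experiment-level structure mirrors flow-cell injection assays: each molecule
evolves under a pre-injection scheme, and with probability
``responder_fraction`` it switches to a post-injection scheme after an
optional exponentially distributed delay.  Photobleaching of either
fluorophore can truncate the usable signal.

Shipped schemes
---------------
``Mg30``
    Four conformations N (native, E_FRET 0.25), F (folded, 0.47),
    C (compact, 0.58), E (extended, 0.12).  Post-injection rates
    k(F->C) = 0.67, k(C->F) = 7.24, k(F->E) = 0.015, k(E->F) = 0.19 1/s;
    C<->E interconversion is left at 0 (too rarely observed to quantify).
``NoDivalent``
    N, C, E dynamics without divalent ions: k(N->C) = 0.36,
    k(C->N) = 2.74, k(N->E) = 0.33, k(E->N) = 0.58 1/s.
``UO2``
    Uranyl-induced extension: native level 0.24 dropping to an extended
    0.11; the post-injection scheme simply starts (and stays) extended.
``Native``
    A single static N state, used as the pre-injection scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .trace_io import Trace, TraceSet

__all__ = [
    "StateSpec",
    "KineticScheme",
    "StatePath",
    "SimConfig",
    "TraceTruth",
    "CANONICAL_LEVELS",
    "default_scheme",
    "simulate_ctmc_path",
    "render_trace",
    "simulate_experiment",
]

#: Canonical mean FRET efficiency of each named conformation.
CANONICAL_LEVELS: dict[str, float] = {"N": 0.25, "F": 0.47, "C": 0.58, "E": 0.12}

#: Default per-state emission SD in E units (histogram peak width).
DEFAULT_SD_E = 0.05


@dataclass(frozen=True)
class StateSpec:
    """One conformational state: label, mean FRET efficiency, emission SD."""

    label: str
    mean_E: float
    sd_E: float = DEFAULT_SD_E


@dataclass
class KineticScheme:
    """States, first-order interconversion rates, and an initial distribution.

    ``rates`` maps ordered label pairs ``(i, j)`` to rate constants in 1/s;
    absent pairs mean no direct interconversion.  The initial distribution
    defaults to uniform over states.
    """

    states: list[StateSpec]
    rates: dict[tuple[str, str], float] = field(default_factory=dict)
    initial_distribution: np.ndarray | None = None

    def __post_init__(self) -> None:
        labels = [s.label for s in self.states]
        if len(set(labels)) != len(labels):
            raise ValueError(f"state labels not unique: {labels}")
        for s in self.states:
            if not np.isfinite(s.mean_E):
                raise ValueError(f"state {s.label}: mean_E must be finite")
            if not s.sd_E > 0:
                raise ValueError(f"state {s.label}: sd_E must be > 0")
        for (i, j), k in self.rates.items():
            if i == j:
                raise ValueError(f"self-rate ({i},{j}) not allowed")
            if i not in labels or j not in labels:
                raise ValueError(f"rate ({i},{j}) refers to unknown state")
            if k < 0:
                raise ValueError(f"rate ({i},{j}) must be >= 0, got {k}")
        if self.initial_distribution is None:
            self.initial_distribution = np.full(len(labels), 1.0 / len(labels))
        self.initial_distribution = np.asarray(self.initial_distribution, float)
        if self.initial_distribution.shape != (len(labels),):
            raise ValueError("initial_distribution length must match states")
        if np.any(self.initial_distribution < 0) or abs(
            self.initial_distribution.sum() - 1.0
        ) > 1e-12:
            raise ValueError("initial_distribution must be a probability vector")

    # -- introspection -----------------------------------------------------

    @property
    def labels(self) -> list[str]:
        return [s.label for s in self.states]

    @property
    def n_states(self) -> int:
        return len(self.states)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def state(self, label: str) -> StateSpec:
        return self.states[self.index(label)]

    def rate_matrix(self) -> np.ndarray:
        """The CTMC generator Q: off-diagonal k_ij, rows summing to zero."""
        k = self.n_states
        Q = np.zeros((k, k))
        for (i, j), r in self.rates.items():
            Q[self.index(i), self.index(j)] = r
        np.fill_diagonal(Q, -Q.sum(axis=1))
        return Q

    def stationary_distribution(self) -> np.ndarray:
        """Solve pi Q = 0, sum(pi) = 1 (least-squares for reducible chains)."""
        Q = self.rate_matrix()
        k = self.n_states
        A = np.vstack([Q.T, np.ones(k)])
        b = np.zeros(k + 1)
        b[-1] = 1.0
        pi, *_ = np.linalg.lstsq(A, b, rcond=None)
        pi = np.clip(pi, 0, None)
        return pi / pi.sum()

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "states": [
                {"label": s.label, "mean_E": s.mean_E, "sd_E": s.sd_E}
                for s in self.states
            ],
            "rates": {f"{i}->{j}": k for (i, j), k in self.rates.items()},
            "initial_distribution": list(map(float, self.initial_distribution)),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "KineticScheme":
        states = [
            StateSpec(s["label"], float(s["mean_E"]), float(s.get("sd_E", DEFAULT_SD_E)))
            for s in d["states"]
        ]
        rates = {}
        for key, k in d.get("rates", {}).items():
            i, j = (part.strip() for part in key.split("->"))
            rates[(i, j)] = float(k)
        init = d.get("initial_distribution")
        return cls(states=states, rates=rates,
                   initial_distribution=None if init is None else np.asarray(init, float))


def _delta(label: str, level: float) -> KineticScheme:
    return KineticScheme(
        states=[StateSpec(label, level)], initial_distribution=np.array([1.0])
    )


def default_scheme(name: str) -> KineticScheme:
    """Return a shipped scheme by name (see module docstring)."""
    if name == "Mg30":
        return KineticScheme(
            states=[
                StateSpec("N", CANONICAL_LEVELS["N"]),
                StateSpec("F", CANONICAL_LEVELS["F"]),
                StateSpec("C", CANONICAL_LEVELS["C"]),
                StateSpec("E", CANONICAL_LEVELS["E"]),
            ],
            rates={
                ("F", "C"): 0.67,
                ("C", "F"): 7.24,
                ("F", "E"): 0.015,
                ("E", "F"): 0.19,
            },
            # entered through folding: all mass on F
            initial_distribution=np.array([0.0, 1.0, 0.0, 0.0]),
        )
    if name == "NoDivalent":
        return KineticScheme(
            states=[
                StateSpec("N", CANONICAL_LEVELS["N"]),
                StateSpec("C", CANONICAL_LEVELS["C"]),
                StateSpec("E", CANONICAL_LEVELS["E"]),
            ],
            rates={
                ("N", "C"): 0.36,
                ("C", "N"): 2.74,
                ("N", "E"): 0.33,
                ("E", "N"): 0.58,
            },
            initial_distribution=np.array([1.0, 0.0, 0.0]),
        )
    if name == "UO2":
        # uranyl binding extends the molecule and keeps it extended
        return _delta("E", 0.11)
    if name == "Native":
        return _delta("N", CANONICAL_LEVELS["N"])
    raise KeyError(f"unknown scheme {name!r}")


# ---------------------------------------------------------------------------
# State paths
# ---------------------------------------------------------------------------


@dataclass
class StatePath:
    """A piecewise-constant conformational trajectory.

    Segments tile ``[t_start[0], t_end[-1]]`` exactly; consecutive segments
    carry different states.  Emission parameters are resolved per segment so
    paths from different schemes can be concatenated.
    """

    labels: list[str]
    t_start: np.ndarray
    t_end: np.ndarray
    mean_E: np.ndarray
    sd_E: np.ndarray

    @property
    def duration(self) -> float:
        return float(self.t_end[-1] - self.t_start[0])

    def shifted(self, offset: float) -> "StatePath":
        return StatePath(
            list(self.labels),
            self.t_start + offset,
            self.t_end + offset,
            self.mean_E.copy(),
            self.sd_E.copy(),
        )

    @staticmethod
    def concatenate(parts: Sequence["StatePath"]) -> "StatePath":
        labels: list[str] = []
        t0, t1, mE, sE = [], [], [], []
        for p in parts:
            for i in range(len(p.labels)):
                # merge identical adjacent states across the seam
                if labels and labels[-1] == p.labels[i] and np.isclose(t1[-1], p.t_start[i]):
                    t1[-1] = p.t_end[i]
                    continue
                labels.append(p.labels[i])
                t0.append(p.t_start[i])
                t1.append(p.t_end[i])
                mE.append(p.mean_E[i])
                sE.append(p.sd_E[i])
        return StatePath(labels, np.array(t0), np.array(t1), np.array(mE), np.array(sE))

    def dominant_frame_labels(self, n_frames: int, frame_period: float) -> list[str]:
        """Label each frame by the state occupying most of its duration."""
        edges = np.arange(n_frames + 1) * frame_period
        # segment index containing each frame's start / end
        first = np.minimum(
            np.searchsorted(self.t_end, edges[:-1], side="right"), len(self.labels) - 1
        )
        last = np.minimum(
            np.searchsorted(self.t_end, edges[1:], side="left"), len(self.labels) - 1
        )
        seg_of_frame = first.copy()
        for f in np.nonzero(first != last)[0]:  # frames spanning a switch (few)
            lo = np.maximum(self.t_start[first[f] : last[f] + 1], edges[f])
            hi = np.minimum(self.t_end[first[f] : last[f] + 1], edges[f + 1])
            seg_of_frame[f] = first[f] + int(np.argmax(hi - lo))
        return [self.labels[s] for s in seg_of_frame]


def simulate_ctmc_path(
    scheme: KineticScheme, duration: float, rng: np.random.Generator
) -> StatePath:
    """Exact Gillespie sample of the scheme's CTMC over ``[0, duration]``.

    The waiting time in state ``i`` is exponential with the total exit rate
    ``sum_j k_ij`` and the successor is drawn proportionally to ``k_ij``.
    An absorbing state yields a single terminal segment.
    """
    if not duration > 0:
        raise ValueError("duration must be > 0")
    Q = scheme.rate_matrix()
    exit_rates = -np.diag(Q)
    n = scheme.n_states
    # row-normalized jump probabilities
    jump = np.zeros((n, n))
    for i in range(n):
        if exit_rates[i] > 0:
            jump[i] = Q[i] / exit_rates[i]
            jump[i, i] = 0.0

    state = int(rng.choice(n, p=scheme.initial_distribution))
    t = 0.0
    labels, t0s, t1s = [], [], []
    while t < duration:
        lam = exit_rates[state]
        dt = rng.exponential(1.0 / lam) if lam > 0 else np.inf
        t_next = min(t + dt, duration)
        labels.append(scheme.labels[state])
        t0s.append(t)
        t1s.append(t_next)
        t = t_next
        if t >= duration:
            break
        state = int(rng.choice(n, p=jump[state]))
    mE = np.array([scheme.state(l).mean_E for l in labels])
    sE = np.array([scheme.state(l).sd_E for l in labels])
    return StatePath(labels, np.array(t0s), np.array(t1s), mE, sE)


def _frame_average(path: StatePath, values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Exact time-weighted average of per-segment ``values`` over each frame.

    Uses the running integral of the piecewise-constant value function,
    which is piecewise linear in time, so linear interpolation at the frame
    edges is exact.
    """
    bp = np.concatenate(([path.t_start[0]], path.t_end))
    cum = np.concatenate(([0.0], np.cumsum(values * (path.t_end - path.t_start))))
    integral = np.interp(edges, bp, cum)
    return np.diff(integral) / np.diff(edges)


# ---------------------------------------------------------------------------
# Rendering and experiments
# ---------------------------------------------------------------------------


@dataclass
class SimConfig:
    """Parameters of a simulated injection experiment.

    Defaults reflect a typical camera-based smFRET setup: 50 ms frames, a
    few hundred counts of total intensity per frame with ~10% molecule-to-
    molecule spread, and modest additive read noise per channel.
    """

    pre_scheme: KineticScheme
    post_scheme: KineticScheme | None = None
    injection_frame: int | None = None
    n_traces: int = 100
    n_frames: int = 1000
    frame_period: float = 0.05
    substeps_per_frame: int = 10
    total_intensity_mean: float = 500.0
    total_intensity_sd: float = 50.0
    channel_noise_sd: float = 10.0
    donor_bleach_rate: float = 0.0
    acceptor_bleach_rate: float = 0.0
    responder_fraction: float = 1.0
    delay_rate: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.responder_fraction <= 1.0:
            raise ValueError("responder_fraction must be in [0, 1]")
        if self.n_traces < 1 or self.n_frames < 1 or self.substeps_per_frame < 1:
            raise ValueError("counts must be >= 1")
        if self.frame_period <= 0:
            raise ValueError("frame_period must be > 0")
        for name in ("donor_bleach_rate", "acceptor_bleach_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.delay_rate is not None and self.delay_rate <= 0:
            raise ValueError("delay_rate must be > 0 when given")
        if self.post_scheme is not None and self.injection_frame is None:
            raise ValueError("post_scheme requires injection_frame")
        if self.injection_frame is not None and not (
            0 <= self.injection_frame < self.n_frames
        ):
            raise ValueError("injection_frame outside trace")


@dataclass
class TraceTruth:
    """Ground truth for one simulated molecule."""

    trace_id: str
    path: StatePath
    responder: bool | None
    delay_s: float | None
    switch_time: float | None
    donor_bleach_frame: int | None
    acceptor_bleach_frame: int | None
    frame_labels: list[str]


def render_trace(
    path: StatePath,
    scheme: KineticScheme,
    cfg: SimConfig,
    rng: np.random.Generator,
    trace_id: str = "sim-0",
    condition: str = "",
    donor_bleach_frame: int | None = None,
    acceptor_bleach_frame: int | None = None,
) -> Trace:
    """Render a state path into a two-channel intensity trace.

    The noiseless frame efficiency is the exact time integral of the state
    means over the frame (a state switch halfway through a frame gives the
    arithmetic mean of the two levels); state-level jitter is one Gaussian
    draw per frame with the occupancy-weighted ``sd_E``.  ``scheme`` is only
    used for bookkeeping — emission parameters ride on the path itself.
    """
    n = cfg.n_frames
    dt = cfg.frame_period
    if path.duration + 1e-9 < n * dt:
        raise ValueError("path shorter than the requested trace")
    edges = np.arange(n + 1) * dt
    e_true = _frame_average(path, path.mean_E, edges)
    sd_frame = _frame_average(path, path.sd_E, edges)
    e = e_true + rng.normal(0.0, 1.0, n) * sd_frame

    i_total = max(rng.normal(cfg.total_intensity_mean, cfg.total_intensity_sd), 1.0)
    acceptor = e * i_total
    donor = (1.0 - e) * i_total

    if acceptor_bleach_frame is not None:
        sl = slice(acceptor_bleach_frame, donor_bleach_frame)
        acceptor[sl] = 0.0
        donor[sl] = i_total
    if donor_bleach_frame is not None:
        acceptor[donor_bleach_frame:] = 0.0
        donor[donor_bleach_frame:] = 0.0

    if cfg.channel_noise_sd > 0:
        acceptor = acceptor + rng.normal(0.0, cfg.channel_noise_sd, n)
        donor = donor + rng.normal(0.0, cfg.channel_noise_sd, n)

    return Trace(
        trace_id=trace_id,
        donor=donor,
        acceptor=acceptor,
        frame_period=dt,
        injection_frame=cfg.injection_frame,
        condition=condition,
    )


def _bleach_frame(rate: float, n_frames: int, dt: float, rng) -> int | None:
    if rate <= 0:
        return None
    t = rng.exponential(1.0 / rate)
    f = int(t / dt)
    return f if f < n_frames else None


def simulate_experiment(cfg: SimConfig) -> tuple[TraceSet, list[TraceTruth]]:
    """Simulate a full injection experiment; fully reproducible from ``cfg.seed``.

    Each molecule evolves under ``pre_scheme`` until the injection time;
    with probability ``responder_fraction`` it switches to ``post_scheme``
    after an optional exponential delay (rate ``delay_rate``), otherwise it
    continues under the pre-injection scheme.  Returns the rendered traces
    and a per-molecule ground-truth record.
    """
    master = np.random.default_rng(cfg.seed)
    children = master.spawn(cfg.n_traces)
    duration = cfg.n_frames * cfg.frame_period
    inj_t = None if cfg.injection_frame is None else cfg.injection_frame * cfg.frame_period

    traces: list[Trace] = []
    truths: list[TraceTruth] = []
    for m, rng in enumerate(children):
        tid = f"sim-{m:04d}"
        responder: bool | None = None
        delay: float | None = None
        switch_time: float | None = None

        if cfg.post_scheme is not None:
            responder = bool(rng.random() < cfg.responder_fraction)
            if responder:
                delay = rng.exponential(1.0 / cfg.delay_rate) if cfg.delay_rate else 0.0
                switch_time = inj_t + delay
                if switch_time >= duration:
                    # response never arrives within the recording
                    responder = False
                    delay = None
                    switch_time = None

        if switch_time is None:
            path = simulate_ctmc_path(cfg.pre_scheme, duration, rng)
        else:
            pre = simulate_ctmc_path(cfg.pre_scheme, switch_time, rng)
            post = simulate_ctmc_path(
                cfg.post_scheme, duration - switch_time, rng
            ).shifted(switch_time)
            path = StatePath.concatenate([pre, post])

        d_bleach = _bleach_frame(cfg.donor_bleach_rate, cfg.n_frames, cfg.frame_period, rng)
        a_bleach = _bleach_frame(cfg.acceptor_bleach_rate, cfg.n_frames, cfg.frame_period, rng)
        if d_bleach is not None and a_bleach is not None and a_bleach >= d_bleach:
            a_bleach = None  # acceptor loss after donor loss is unobservable

        scheme = cfg.post_scheme if cfg.post_scheme is not None else cfg.pre_scheme
        traces.append(
            render_trace(
                path,
                scheme,
                cfg,
                rng,
                trace_id=tid,
                donor_bleach_frame=d_bleach,
                acceptor_bleach_frame=a_bleach,
            )
        )
        truths.append(
            TraceTruth(
                trace_id=tid,
                path=path,
                responder=responder,
                delay_s=delay,
                switch_time=switch_time,
                donor_bleach_frame=d_bleach,
                acceptor_bleach_frame=a_bleach,
                frame_labels=path.dominant_frame_labels(cfg.n_frames, cfg.frame_period),
            )
        )
    return TraceSet(traces=traces), truths
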