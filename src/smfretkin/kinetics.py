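"""Dwell-time extraction, exponential rate fitting, and transition summaries.

Dwells
------
Maximal constant-label runs of an idealized path become :class:`DwellRecord`
sojourns.  Runs shorter than ``min_frames`` are treated as detection
flickers: they are removed and their neighbors merged when the neighbors
share a label (otherwise the blip leaves a censoring gap).  A dwell is
censored on any side that abuts a trace boundary, a mask gap, an injection
split, or a bleach point; censored sides carry no exit information.

Rates
-----
Dwell durations in a state are exponential, so the maximum-likelihood
single-exponential fit is the reciprocal mean of the complete (uncensored)
durations; a histogram least-squares fit is provided for parity with
histogram-based workflows.  Per-pair rate constants split a state's total
exit rate by its branching fractions.

Because dwells are measured in whole camera frames, short sojourns bias the
naive reciprocal mean: a state whose mean dwell is a few frames yields
geometrically distributed frame counts, and events shorter than the
detection dead time vanish altogether, silently merging the flanking
dwells.  ``build_rate_table`` therefore (by default) fits the frame-count
distribution as a geometric law above the dead time — the discrete-time
analogue of the single-exponential fit, exact for sampled Markov chains —
and corrects both the undercounted transitions into fast states and the
apparent slowing of states whose excursions go undetected.  Rate pairs
observed in fewer than ``min_molecules`` molecules are excluded (reported,
not fitted), mirroring the practice of dropping transition classes seen in
only a handful of traces.

Transition summaries
--------------------
The transition density plot (TDP) is the 2-D histogram of
(E before, E after) over transition events, normalized to the total count.
The transition occupancy density plot (TODP) weights each *molecule* once
per unordered transition class, i.e. the fraction of molecules exhibiting
that class, so a single hyperactive molecule cannot dominate the map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .hmm import IdealizedPath

__all__ = [
    "DwellRecord",
    "TransitionRecord",
    "RateEntry",
    "RateTable",
    "ExponentialFit",
    "TooFewDwellsError",
    "extract_dwells",
    "fit_exponential",
    "build_rate_table",
    "self_calibrate_rates",
    "build_tdp",
    "build_todp",
    "state_histogram",
    "TDP",
    "TODP",
    "StateHistogram",
]


class TooFewDwellsError(ValueError):
    """Not enough complete dwells to support a rate fit."""


@dataclass
class DwellRecord:
    """One sojourn in one state (half-open frame range)."""

    trace_id: str
    state_label: str
    start_frame: int
    end_frame: int
    duration: float  # seconds
    prev_state: str | None
    next_state: str | None
    censored_left: bool
    censored_right: bool

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame


@dataclass
class TransitionRecord:
    """One state switch, with the fitted emission means on both sides."""

    trace_id: str
    from_label: str
    to_label: str
    frame: int  # first frame of the destination dwell
    E_before: float = float("nan")
    E_after: float = float("nan")


@dataclass
class ExponentialFit:
    k: float  # 1/s
    ci95: tuple[float, float] | None
    n: int
    method: str


@dataclass
class RateEntry:
    k: float | None
    n_transitions: int
    n_molecules: int
    ci95: tuple[float, float] | None = None
    excluded: bool = False
    reason: str | None = None


@dataclass
class RateTable:
    """Per ordered state pair: rate constant, counts, CI, exclusion flag."""

    entries: dict[tuple[str, str], RateEntry]
    frame_period: float
    n_molecules_total: int

    def rate(self, i: str, j: str) -> float:
        e = self.entries[(i, j)]
        if e.excluded or e.k is None:
            raise KeyError(f"rate {i}->{j} is excluded: {e.reason}")
        return e.k

    def included(self) -> dict[tuple[str, str], RateEntry]:
        return {p: e for p, e in self.entries.items() if not e.excluded}

    def to_dict(self) -> dict:
        return {
            f"{i}->{j}": {
                "k_per_s": e.k,
                "n_transitions": e.n_transitions,
                "n_molecules": e.n_molecules,
                "ci95": list(e.ci95) if e.ci95 else None,
                "excluded": e.excluded,
                "reason": e.reason,
            }
            for (i, j), e in self.entries.items()
        }


# ---------------------------------------------------------------------------
# Dwell extraction
# ---------------------------------------------------------------------------


def _runs(labels: list[str], lo: int, hi: int) -> list[list]:
    out: list[list] = []
    for f in range(lo, hi):
        if out and out[-1][0] == labels[f - lo] and out[-1][2] == f:
            out[-1][2] = f + 1
        else:
            out.append([labels[f - lo], f, f + 1])
    return out


def _suppress_flickers(runs: list[list], min_frames: int) -> tuple[list[list], list[tuple[int, int]]]:
    """Drop runs shorter than ``min_frames``; merge same-labeled neighbors.

    Returns the surviving runs and the frame ranges removed as unusable
    gaps (blips whose neighbors disagree).
    """
    runs = [list(r) for r in runs]
    gaps: list[tuple[int, int]] = []
    changed = True
    while changed:
        changed = False
        for i, (lab, s, e) in enumerate(runs):
            if e - s >= min_frames:
                continue
            left = runs[i - 1] if i > 0 else None
            right = runs[i + 1] if i + 1 < len(runs) else None
            if left is not None and right is not None and left[0] == right[0]:
                # merge left + blip + right into one dwell
                left[2] = right[2]
                del runs[i : i + 2]
            else:
                gaps.append((s, e))
                del runs[i]
            changed = True
            break
    return runs, gaps


def extract_dwells(
    path: IdealizedPath,
    min_frames: int = 2,
    state_means: dict[str, float] | None = None,
) -> tuple[list[DwellRecord], list[TransitionRecord]]:
    """Turn an idealized path into dwell and transition records.

    Each decoded segment of the path is processed independently; segment
    edges censor the abutting dwells.  ``state_means`` (label -> fitted E)
    populates the transition records' before/after levels when given.
    """
    dt = path.frame_period
    if path.state_labels is not None:
        lab = lambda s: path.state_labels.get(int(s), str(int(s)))
    else:
        lab = lambda s: str(int(s))
    mean_of = (lambda l: state_means.get(l, float("nan"))) if state_means else (
        lambda l: float("nan")
    )

    dwells: list[DwellRecord] = []
    transitions: list[TransitionRecord] = []
    segments = path.segments
    if not segments:
        segments = [] if np.all(path.states < 0) else [(0, path.n_frames)]
    for lo, hi in segments:
        labels = [lab(s) for s in path.states[lo:hi]]
        if any(path.states[lo:hi] < 0):
            raise ValueError("decoded segment contains invalid frames")
        runs, gaps = _suppress_flickers(_runs(labels, lo, hi), min_frames)
        gap_edges = {g[0] for g in gaps} | {g[1] for g in gaps}
        for i, (label, s, e) in enumerate(runs):
            left = runs[i - 1] if i > 0 else None
            right = runs[i + 1] if i + 1 < len(runs) else None
            contig_left = left is not None and left[2] == s
            contig_right = right is not None and right[1] == e
            dwells.append(
                DwellRecord(
                    trace_id=path.trace_id,
                    state_label=label,
                    start_frame=s,
                    end_frame=e,
                    duration=(e - s) * dt,
                    prev_state=left[0] if contig_left else None,
                    next_state=right[0] if contig_right else None,
                    censored_left=not contig_left,
                    censored_right=not contig_right,
                )
            )
            if contig_right:
                transitions.append(
                    TransitionRecord(
                        trace_id=path.trace_id,
                        from_label=label,
                        to_label=right[0],
                        frame=e,
                        E_before=mean_of(label),
                        E_after=mean_of(right[0]),
                    )
                )
        del gap_edges  # bookkeeping only; censoring follows from contiguity
    return dwells, transitions


# ---------------------------------------------------------------------------
# Exponential fitting
# ---------------------------------------------------------------------------


def _complete(dwells) -> list[DwellRecord]:
    return [d for d in dwells if not d.censored_left and not d.censored_right]


def fit_exponential(
    dwells: list[DwellRecord],
    method: str = "mle",
    bootstrap_n: int = 200,
    min_dwells: int = 10,
    seed: int = 0,
) -> ExponentialFit:
    """Single-exponential fit of the complete dwell durations in one state.

    ``mle`` returns the reciprocal mean (the exact maximum-likelihood
    estimator for exponential data); ``histogram_lsq`` least-squares fits
    ``c * exp(-k t)`` to a Freedman-Diaconis histogram (minimum 5 bins).
    The 95% CI is a nonparametric bootstrap over molecules.
    """
    comp = _complete(dwells)
    if len(comp) < min_dwells:
        raise TooFewDwellsError(
            f"{len(comp)} complete dwells < required {min_dwells}"
        )
    durations = np.array([d.duration for d in comp])
    mols = np.array([d.trace_id for d in comp])

    def estimate(dur: np.ndarray) -> float:
        if method == "mle":
            return 1.0 / dur.mean()
        if method == "histogram_lsq":
            edges = np.histogram_bin_edges(dur, bins="fd")
            if len(edges) < 6:
                edges = np.histogram_bin_edges(dur, bins=5)
            counts, edges = np.histogram(dur, bins=edges)
            centers = 0.5 * (edges[:-1] + edges[1:])
            k0 = 1.0 / dur.mean()
            popt, _ = curve_fit(
                lambda t, c, k: c * np.exp(-k * t),
                centers,
                counts,
                p0=(counts.max(), k0),
                maxfev=10000,
            )
            return float(popt[1])
        raise ValueError(f"unknown method {method!r}")

    k_hat = estimate(durations)

    ci = None
    unique_mols = np.unique(mols)
    if bootstrap_n > 0 and len(unique_mols) > 1:
        rng = np.random.default_rng(seed)
        by_mol = {m: durations[mols == m] for m in unique_mols}
        samples = []
        for _ in range(bootstrap_n):
            pick = rng.choice(unique_mols, size=len(unique_mols), replace=True)
            dur = np.concatenate([by_mol[m] for m in pick])
            try:
                samples.append(estimate(dur))
            except RuntimeError:  # histogram fit failed on a resample
                continue
        if samples:
            ci = tuple(np.percentile(samples, [2.5, 97.5]))
    return ExponentialFit(k=float(k_hat), ci95=ci, n=len(comp), method=method)


# ---------------------------------------------------------------------------
# Rate table
# ---------------------------------------------------------------------------


def _geometric_exit_rate(
    n_exit: np.ndarray, n_censored: np.ndarray, dead: int, dt: float
) -> tuple[float, float]:
    """Total exit rate and dwell-detection probability from frame counts.

    Frame-count dwells of a sampled chain are geometric; by memorylessness
    the counts above the dead time ``d``, shifted by ``d - 1``, follow the
    same geometric law, so the continuation probability ``p`` is estimated
    unbiased by the missing short dwells.  Right-censored dwells (cut by a
    trace end, mask, or bleach) enter through their survival term, which
    removes the length bias against sojourns comparable to the observation
    window.  The censored MLE is ``p = (S - m) / S`` with ``S`` the total
    shifted frame count and ``m`` the number of observed exits; the exit
    rate is ``-ln(p) / dt`` and a dwell survives the dead time with
    probability ``p^(d-1)``.
    """
    kept_exit = n_exit[n_exit >= dead] - (dead - 1)
    kept_cens = n_censored[n_censored >= dead] - (dead - 1)
    m = len(kept_exit)
    s = kept_exit.sum() + kept_cens.sum()
    if m == 0 or s <= m:
        return float("nan"), 1.0
    p = min((s - m) / s, 1.0 - 1e-12)
    p = max(p, 1e-12)
    return -np.log(p) / dt, p ** (dead - 1)


def build_rate_table(
    dwells: list[DwellRecord],
    transitions: list[TransitionRecord],
    frame_period: float | None = None,
    min_molecules: int = 20,
    min_dwells: int = 10,
    dead_frames: int = 2,
    correct_discretization: bool = True,
    bootstrap_n: int = 100,
    seed: int = 0,
) -> RateTable:
    """Fit every observed ordered transition rate from dwell statistics.

    For each state the total exit rate is fitted from its complete dwell
    durations (geometric dead-time fit by default, reciprocal mean with
    ``correct_discretization=False``) and split among destinations by the
    branching fractions; transition counts into fast states are scaled up
    by the destination's dwell-detection probability, and states whose
    short excursions go undetected get their apparent exit rate restored by
    the expected fraction of invisible round trips.  Pairs observed in
    fewer than ``min_molecules`` molecules are reported but excluded.
    """
    if frame_period is None:
        if not dwells:
            raise ValueError("no dwells")
        d0 = dwells[0]
        frame_period = d0.duration / d0.n_frames
    dt = frame_period

    states = sorted({d.state_label for d in dwells})
    pairs = sorted({(t.from_label, t.to_label) for t in transitions})

    mol_ids = sorted({d.trace_id for d in dwells})
    mol_index = {m: i for i, m in enumerate(mol_ids)}
    n_mol = len(mol_ids)

    # per-molecule sufficient statistics for the bootstrap:
    # exit-observed dwells (left censoring is harmless by memorylessness),
    # right-censored dwells (survival only), and fully complete dwells
    # (the plain reciprocal-mean path)
    frames_exit = {s: [[] for _ in range(n_mol)] for s in states}
    frames_cens = {s: [[] for _ in range(n_mol)] for s in states}
    frames_full = {s: [[] for _ in range(n_mol)] for s in states}
    for d in dwells:
        slot = mol_index[d.trace_id]
        if d.censored_right:
            frames_cens[d.state_label][slot].append(d.n_frames)
        else:
            frames_exit[d.state_label][slot].append(d.n_frames)
            if not d.censored_left:
                frames_full[d.state_label][slot].append(d.n_frames)
    counts_by_pair = {p: np.zeros(n_mol) for p in pairs}
    for d in dwells:
        if d.censored_right or d.next_state is None:
            continue
        p = (d.state_label, d.next_state)
        if p in counts_by_pair:
            counts_by_pair[p][mol_index[d.trace_id]] += 1

    def rates_from(mol_pick: np.ndarray) -> dict[tuple[str, str], float]:
        # total exit rate and detection probability per state
        k_tot: dict[str, float] = {}
        phi: dict[str, float] = {}
        for s in states:
            n_exit = np.array(
                [f for m in mol_pick for f in frames_exit[s][m]], dtype=float
            )
            if len(n_exit) < min_dwells:
                k_tot[s] = float("nan")
                phi[s] = 1.0
                continue
            if correct_discretization:
                n_cens = np.array(
                    [f for m in mol_pick for f in frames_cens[s][m]], dtype=float
                )
                k_tot[s], phi[s] = _geometric_exit_rate(
                    n_exit, n_cens, dead_frames, dt
                )
            else:
                n_full = np.array(
                    [f for m in mol_pick for f in frames_full[s][m]], dtype=float
                )
                if len(n_full) < min_dwells:
                    k_tot[s] = float("nan")
                    phi[s] = 1.0
                    continue
                k_tot[s] = 1.0 / (n_full.mean() * dt)
                phi[s] = 1.0
        raw = {p: counts_by_pair[p][mol_pick].sum() for p in pairs}
        # branching fractions with destination-detection correction
        branch: dict[tuple[str, str], float] = {}
        for s in states:
            outs = {p: raw[p] / phi.get(p[1], 1.0) for p in pairs if p[0] == s}
            tot = sum(outs.values())
            for p, v in outs.items():
                branch[p] = v / tot if tot > 0 else float("nan")
        out: dict[tuple[str, str], float] = {}
        for s in states:
            if not np.isfinite(k_tot[s]):
                continue
            # invisible round trips (i -> missed j -> i) inflate i's dwells
            beta = sum(
                branch.get((s, j), 0.0)
                * (1.0 - phi.get(j, 1.0))
                * branch.get((j, s), 0.0)
                for j in states
                if j != s
            )
            k_corr = k_tot[s] / max(1.0 - beta, 1e-6)
            for p in pairs:
                if p[0] == s and np.isfinite(branch.get(p, float("nan"))):
                    out[p] = k_corr * branch[p]
        return out

    all_mols = np.arange(n_mol)
    point = rates_from(all_mols)

    boot: dict[tuple[str, str], list[float]] = {p: [] for p in pairs}
    if bootstrap_n > 0 and n_mol > 1:
        rng = np.random.default_rng(seed)
        for _ in range(bootstrap_n):
            pick = rng.integers(0, n_mol, size=n_mol)
            est = rates_from(pick)
            for p, v in est.items():
                if np.isfinite(v):
                    boot[p].append(v)

    entries: dict[tuple[str, str], RateEntry] = {}
    for p in pairs:
        n_tr = int(counts_by_pair[p].sum())
        n_mols_pair = int(np.count_nonzero(counts_by_pair[p]))
        k = point.get(p)
        excluded = False
        reason = None
        if n_mols_pair < min_molecules:
            excluded = True
            reason = (
                f"observed in {n_mols_pair} molecules "
                f"(< min_molecules = {min_molecules})"
            )
        elif k is None or not np.isfinite(k):
            excluded = True
            reason = f"fewer than {min_dwells} complete dwells in state {p[0]!r}"
        ci = None
        if not excluded and len(boot[p]) >= 20:
            ci = tuple(np.percentile(boot[p], [2.5, 97.5]))
        entries[p] = RateEntry(
            k=None if excluded else float(k),
            n_transitions=n_tr,
            n_molecules=n_mols_pair,
            ci95=ci,
            excluded=excluded,
            reason=reason,
        )
    return RateTable(entries=entries, frame_period=dt, n_molecules_total=n_mol)


# ---------------------------------------------------------------------------
# Simulation-based missed-event calibration
# ---------------------------------------------------------------------------


def self_calibrate_rates(
    observed: RateTable,
    model,
    state_labels: dict[int, str],
    segment_lengths: list[int],
    min_frames: int = 2,
    dead_frames: int = 2,
    correct_discretization: bool = True,
    min_dwells: int = 10,
    n_rounds: int = 2,
    sim_replicates: int = 2,
    seed: int = 0,
    max_factor: float = 3.0,
) -> RateTable:
    """Debias a rate table by parametric simulation through the same pipeline.

    Idealization-based dwell counting has decoder-dependent missed-event
    bias: sojourns near the frame time are absorbed into their neighbors,
    which both undercounts transitions into fast states and stretches the
    apparent dwells of the slow ones.  The closed-form corrections in
    :func:`build_rate_table` assume truncation-like missingness and cannot
    capture what the decoder actually does, so this routine measures the
    bias directly, in the spirit of missed-event corrections in
    single-channel kinetics: synthetic segments matching the observed
    segment lengths are generated from the *fitted* emission model at the
    current rate estimates, refitted and decoded by the identical
    HMM/dwell/rate chain, and each rate is rescaled by the ratio of the
    observed estimate to the estimate the pipeline returns on data whose
    truth is known.  A couple of fixed-point rounds suffice; per-round
    factors are clipped to ``max_factor`` for safety.  The calibration uses
    only the observed data and the fitted model — no external truth.

    ``model``/``state_labels`` are the data-fitted emission model and its
    level labels; ``segment_lengths`` are the decoded chain lengths in
    frames (``sim_replicates`` copies are simulated per round to shrink the
    Monte-Carlo noise of the correction).
    """
    from .hmm import fit_baum_welch, viterbi_all
    from .preprocess import EfretSeries
    from .synth import KineticScheme, StateSpec, simulate_ctmc_path, _frame_average

    dt = observed.frame_period
    means = {lab: float(model.means[i]) for i, lab in state_labels.items()}
    sds = {lab: float(np.sqrt(model.variances[i])) for i, lab in state_labels.items()}

    target = {
        p: e.k for p, e in observed.included().items()
        if p[0] in means and p[1] in means
    }
    if not target:
        return observed
    current = dict(target)
    rng = np.random.default_rng(seed)

    def pipeline_estimate(rates: dict) -> dict:
        labels_used = sorted({s for p in rates for s in p})
        scheme = KineticScheme(
            states=[StateSpec(l, means[l], sds[l]) for l in labels_used],
            rates=dict(rates),
        )
        scheme.initial_distribution = scheme.stationary_distribution()
        sim = []
        lengths = [L for L in segment_lengths if L >= 2] * sim_replicates
        for i, L in enumerate(lengths):
            path = simulate_ctmc_path(scheme, L * dt, rng)
            edges = np.arange(L + 1) * dt
            e = _frame_average(path, path.mean_E, edges)
            e = e + rng.normal(0.0, 1.0, L) * _frame_average(path, path.sd_E, edges)
            sim.append(
                EfretSeries(trace_id=f"cal-{i}", E=e, valid=np.ones(L, bool),
                            frame_period=dt)
            )
        refit = fit_baum_welch(sim, model.k, init=model, tol=1e-6, max_iter=200)
        relabel = {
            i: min(means, key=lambda l: abs(means[l] - mu))
            for i, mu in enumerate(refit.model.means)
        }
        dwells, transitions = [], []
        for p in viterbi_all(refit.model, sim):
            d, t = extract_dwells(p.labeled(relabel), min_frames=min_frames)
            dwells.extend(d)
            transitions.extend(t)
        table = build_rate_table(
            dwells, transitions, frame_period=dt, min_molecules=1,
            min_dwells=min_dwells, dead_frames=dead_frames,
            correct_discretization=correct_discretization, bootstrap_n=0,
        )
        return {p: e.k for p, e in table.included().items()}

    for _ in range(max(n_rounds, 0)):
        sim_est = pipeline_estimate(current)
        for p in list(current):
            if p in sim_est and sim_est[p] and sim_est[p] > 0:
                factor = np.clip(target[p] / sim_est[p], 1.0 / max_factor, max_factor)
                current[p] = current[p] * factor

    entries = {}
    for p, e in observed.entries.items():
        if p in current and not e.excluded and e.k:
            scale = current[p] / e.k
            entries[p] = RateEntry(
                k=float(current[p]),
                n_transitions=e.n_transitions,
                n_molecules=e.n_molecules,
                ci95=tuple(scale * np.asarray(e.ci95)) if e.ci95 else None,
                excluded=False,
                reason=None,
            )
        else:
            entries[p] = e
    return RateTable(entries=entries, frame_period=dt,
                     n_molecules_total=observed.n_molecules_total)


# ---------------------------------------------------------------------------
# TDP / TODP
# ---------------------------------------------------------------------------


@dataclass
class TDP:
    matrix: np.ndarray  # (n_bins, n_bins), rows = E_before
    edges: np.ndarray
    n_transitions: int


@dataclass
class TODP:
    matrix: np.ndarray
    edges: np.ndarray
    classes: dict[tuple[str, str], tuple[int, float]]  # class -> (n_molecules, fraction)
    n_molecules_total: int


def build_tdp(transitions: list[TransitionRecord], bin_width: float = 0.02) -> TDP:
    """Transition density plot: each event adds weight 1 at (E_before, E_after).

    The grid covers [0, 1]^2; the total mass is normalized to 1 when any
    transitions exist.  The diagonal is empty by construction because
    transitions connect distinct states.
    """
    edges = np.arange(0.0, 1.0 + bin_width / 2, bin_width)
    m = np.zeros((len(edges) - 1, len(edges) - 1))
    before = np.array([t.E_before for t in transitions])
    after = np.array([t.E_after for t in transitions])
    ok = np.isfinite(before) & np.isfinite(after)
    if ok.any():
        m, _, _ = np.histogram2d(before[ok], after[ok], bins=[edges, edges])
        m /= m.sum()
    return TDP(matrix=m, edges=edges, n_transitions=int(ok.sum()))


def build_todp(
    transitions: list[TransitionRecord],
    n_molecules_total: int,
    bin_width: float = 0.02,
) -> TODP:
    """Transition occupancy density plot: one vote per molecule per class.

    The unordered class {i, j} receives weight
    ``n_molecules_with_class / n_molecules_total`` in both ordered bins;
    a molecule showing many i<->j transitions still counts once.
    """
    edges = np.arange(0.0, 1.0 + bin_width / 2, bin_width)
    nb = len(edges) - 1
    m = np.zeros((nb, nb))

    level: dict[str, list[float]] = {}
    mols_by_class: dict[tuple[str, str], set] = {}
    for t in transitions:
        cls = tuple(sorted((t.from_label, t.to_label)))
        mols_by_class.setdefault(cls, set()).add(t.trace_id)
        if np.isfinite(t.E_before):
            level.setdefault(t.from_label, []).append(t.E_before)
        if np.isfinite(t.E_after):
            level.setdefault(t.to_label, []).append(t.E_after)
    mean_level = {lab: float(np.mean(v)) for lab, v in level.items()}

    def bin_of(x: float) -> int:
        return int(np.clip(np.searchsorted(edges, x, side="right") - 1, 0, nb - 1))

    classes: dict[tuple[str, str], tuple[int, float]] = {}
    for cls, mols in sorted(mols_by_class.items()):
        frac = len(mols) / n_molecules_total
        classes[cls] = (len(mols), frac)
        a, b = cls
        if a in mean_level and b in mean_level:
            m[bin_of(mean_level[a]), bin_of(mean_level[b])] += frac
            m[bin_of(mean_level[b]), bin_of(mean_level[a])] += frac
    return TODP(matrix=m, edges=edges, classes=classes, n_molecules_total=n_molecules_total)


# ---------------------------------------------------------------------------
# Pooled E histogram with Gaussian peaks
# ---------------------------------------------------------------------------


@dataclass
class StateHistogram:
    counts: np.ndarray
    edges: np.ndarray
    peaks: dict[str, tuple[float, float]]  # label -> (mean, sd)


def state_histogram(
    values: np.ndarray,
    labels: np.ndarray | None = None,
    bins: int | np.ndarray = 50,
    k: int | None = None,
) -> StateHistogram:
    """Pooled E histogram with per-state Gaussian peak parameters.

    With per-value ``labels`` the peaks are the labeled groups' means/SDs;
    otherwise a ``k``-component 1-D Gaussian mixture is fitted by EM.
    """
    raw = np.asarray(values, float)
    finite = np.isfinite(raw)
    values = raw[finite]
    if len(values) == 0:
        raise ValueError("need at least one valid value")
    counts, edges = np.histogram(values, bins=bins)

    peaks: dict[str, tuple[float, float]] = {}
    if labels is not None:
        labels = np.asarray(labels)[finite]
        for lab in np.unique(labels):
            grp = values[labels == lab]
            if len(grp):
                peaks[str(lab)] = (float(np.mean(grp)), float(np.std(grp)))
    else:
        k = k or 1
        mu = np.quantile(values, np.linspace(0.1, 0.9, k))
        var = np.full(k, max(np.var(values) / k, 1e-6))
        w = np.full(k, 1.0 / k)
        for _ in range(200):
            resp = w * np.exp(
                -0.5 * (values[:, None] - mu) ** 2 / var
            ) / np.sqrt(2 * np.pi * var)
            resp /= np.maximum(resp.sum(axis=1, keepdims=True), 1e-300)
            tot = resp.sum(axis=0)
            mu_new = resp.T @ values / tot
            var_new = np.maximum(
                (resp * (values[:, None] - mu_new) ** 2).sum(axis=0) / tot, 1e-8
            )
            w = tot / len(values)
            if np.max(np.abs(mu_new - mu)) < 1e-8:
                mu, var = mu_new, var_new
                break
            mu, var = mu_new, var_new
        for i in range(k):
            peaks[f"peak{i}"] = (float(mu[i]), float(np.sqrt(var[i])))
    return StateHistogram(counts=counts, edges=edges, peaks=peaks)
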