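"""Hidden-Markov idealization of FRET-efficiency series.

The emission model is a 1-D Gaussian per hidden state on the per-frame
efficiency E (camera-integrated trajectories are analyzed on the E axis,
not on the raw channel intensities).  One *global* model is fitted per
condition by pooling every molecule's valid segments — pooling matches
per-condition rate reporting and stabilizes rarely visited states — and
each molecule is then decoded individually with the Viterbi algorithm.

Numerics: the forward/backward recursions use per-frame scaling, which is
exactly equivalent to log-space accumulation but vectorizes across
molecules.  Segments of unequal length are right-padded with unit emission
likelihood; with a row-stochastic transition matrix such padding leaves
every scaled quantity and the total likelihood untouched, so a single
(n_segments, T_max) batch processes the whole data set.  Invalid frames
(masked, bleached, direct excitation) break the chain: decoding restarts
from the initial distribution after every gap.

Expectation-maximization never decreases the pooled log-likelihood;
convergence is declared when the relative improvement drops below ``tol``.
A variance floor (1e-6 E^2) prevents collapse on noiseless fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from .preprocess import EfretSeries
from .synth import CANONICAL_LEVELS

__all__ = [
    "HmmModel",
    "HmmFit",
    "IdealizedPath",
    "DegenerateModelError",
    "AmbiguousLabelError",
    "fit_baum_welch",
    "viterbi",
    "viterbi_all",
    "select_k",
    "map_states_to_levels",
    "count_switches",
]

_VAR_FLOOR = 1e-6
_TINY = 1e-300


class DegenerateModelError(RuntimeError):
    """A state captured (nearly) no probability mass; refit with smaller K."""


class AmbiguousLabelError(ValueError):
    """Two fitted states map to the same canonical level."""


@dataclass
class HmmModel:
    """Gaussian-emission HMM parameters on the E_FRET axis."""

    means: np.ndarray
    variances: np.ndarray
    transmat: np.ndarray
    startprob: np.ndarray

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, float)
        self.variances = np.asarray(self.variances, float)
        self.transmat = np.asarray(self.transmat, float)
        self.startprob = np.asarray(self.startprob, float)
        k = len(self.means)
        if k < 1:
            raise ValueError("need at least one state")
        if self.variances.shape != (k,) or np.any(self.variances <= 0):
            raise ValueError("variances must be positive, one per state")
        if not np.all(np.isfinite(self.means)):
            raise ValueError("means must be finite")
        if self.transmat.shape != (k, k) or np.any(self.transmat < 0):
            raise ValueError("transmat must be a nonnegative KxK matrix")
        if np.max(np.abs(self.transmat.sum(axis=1) - 1.0)) > 1e-9:
            raise ValueError("transmat rows must sum to 1")
        if self.startprob.shape != (k,) or abs(self.startprob.sum() - 1.0) > 1e-9:
            raise ValueError("startprob must be a probability vector")

    @property
    def k(self) -> int:
        return len(self.means)

    @property
    def n_parameters(self) -> int:
        # (K-1) start + K(K-1) transitions + 2K emissions = K^2 + 2K - 1
        return self.k * self.k + 2 * self.k - 1

    def permuted(self, order: Sequence[int]) -> "HmmModel":
        order = np.asarray(order)
        return HmmModel(
            means=self.means[order],
            variances=self.variances[order],
            transmat=self.transmat[np.ix_(order, order)],
            startprob=self.startprob[order],
        )


@dataclass
class HmmFit:
    model: HmmModel
    log_likelihood: float
    history: list[float]
    converged: bool
    n_iter: int


@dataclass
class IdealizedPath:
    """Per-frame state assignment of one molecule.

    ``states[f]`` is the decoded state index or -1 on invalid frames.
    ``segments`` are the half-open frame ranges that were decoded as
    unbroken chains; their edges act as censoring boundaries downstream.
    """

    trace_id: str
    states: np.ndarray
    frame_period: float
    log_likelihood: float
    state_labels: dict[int, str] | None = None
    segments: list[tuple[int, int]] = field(default_factory=list)

    @property
    def n_frames(self) -> int:
        return len(self.states)

    def labeled(self, state_labels: dict[int, str]) -> "IdealizedPath":
        out = IdealizedPath(
            trace_id=self.trace_id,
            states=self.states.copy(),
            frame_period=self.frame_period,
            log_likelihood=self.log_likelihood,
            state_labels=dict(state_labels),
            segments=list(self.segments),
        )
        return out


# ---------------------------------------------------------------------------
# Segment collection and padding
# ---------------------------------------------------------------------------


def _valid_runs(valid: np.ndarray, lo: int, hi: int) -> list[tuple[int, int]]:
    runs = []
    f = lo
    while f < hi:
        if valid[f]:
            g = f
            while g < hi and valid[g]:
                g += 1
            runs.append((f, g))
            f = g
        else:
            f += 1
    return runs


def _series_segments(e: EfretSeries) -> list[tuple[int, int]]:
    """Contiguous valid runs intersected with the analysis segments."""
    bounds = e.analysis_segments or [(0, e.n_frames)]
    out: list[tuple[int, int]] = []
    for lo, hi in bounds:
        out.extend(_valid_runs(e.valid, lo, hi))
    return out


def _collect(series) -> tuple[list[np.ndarray], list[tuple[int, int, int]]]:
    """Flatten input into per-segment value arrays.

    Accepts :class:`EfretSeries` objects or bare arrays (finite runs are the
    segments).  Returns the segment values and ``(series_idx, start, end)``
    provenance tuples.
    """
    values: list[np.ndarray] = []
    prov: list[tuple[int, int, int]] = []
    for idx, s in enumerate(series):
        if isinstance(s, EfretSeries):
            for lo, hi in _series_segments(s):
                values.append(s.E[lo:hi])
                prov.append((idx, lo, hi))
        else:
            arr = np.asarray(s, float)
            for lo, hi in _valid_runs(np.isfinite(arr), 0, len(arr)):
                values.append(arr[lo:hi])
                prov.append((idx, lo, hi))
    return values, prov


def _pad(values: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    n = len(values)
    t_max = max(len(v) for v in values)
    x = np.zeros((n, t_max))
    mask = np.zeros((n, t_max), bool)
    for i, v in enumerate(values):
        x[i, : len(v)] = v
        mask[i, : len(v)] = True
    return x, mask


def _emission_lik(x: np.ndarray, mask: np.ndarray, model: HmmModel) -> np.ndarray:
    """Gaussian emission likelihoods, shape (N, T, K); 1 on padded frames."""
    diff = x[:, :, None] - model.means[None, None, :]
    var = model.variances[None, None, :]
    b = np.exp(-0.5 * diff * diff / var) / np.sqrt(2.0 * np.pi * var)
    b[~mask] = 1.0
    return np.maximum(b, _TINY)


# ---------------------------------------------------------------------------
# Forward / backward / EM
# ---------------------------------------------------------------------------


def _forward_backward(b: np.ndarray, mask: np.ndarray, model: HmmModel):
    """Scaled forward-backward over a padded batch.

    Returns (alpha, beta, c, loglik): scaled forward/backward variables,
    per-frame scaling factors, and the total log-likelihood over valid
    frames.
    """
    n, t_max, k = b.shape
    A = model.transmat
    alpha = np.empty((n, t_max, k))
    c = np.empty((n, t_max))

    a = model.startprob[None, :] * b[:, 0, :]
    c[:, 0] = a.sum(axis=1)
    alpha[:, 0] = a / c[:, 0, None]
    for t in range(1, t_max):
        a = (alpha[:, t - 1] @ A) * b[:, t]
        c[:, t] = a.sum(axis=1)
        alpha[:, t] = a / c[:, t, None]

    beta = np.empty((n, t_max, k))
    beta[:, -1] = 1.0
    for t in range(t_max - 2, -1, -1):
        beta[:, t] = ((b[:, t + 1] * beta[:, t + 1]) @ A.T) / c[:, t + 1, None]

    loglik = float(np.log(c[mask]).sum())
    return alpha, beta, c, loglik


def _em_step(x, mask, model: HmmModel, var_floor: float):
    b = _emission_lik(x, mask, model)
    alpha, beta, c, loglik = _forward_backward(b, mask, model)

    gamma = alpha * beta
    gamma /= np.maximum(gamma.sum(axis=2, keepdims=True), _TINY)
    gamma[~mask] = 0.0

    # transition expectations over valid steps (t -> t+1 with t+1 in-segment)
    step_ok = mask[:, 1:]
    w = (b[:, 1:] * beta[:, 1:]) / c[:, 1:, None]
    w[~step_ok] = 0.0
    a_num = np.einsum("nti,ntj,ij->ij", alpha[:, :-1], w, model.transmat)
    a_num = np.maximum(a_num, 0.0)

    occ = gamma.sum(axis=(0, 1))
    if np.any(occ < 1.0):
        lo = int(np.argmin(occ))
        raise DegenerateModelError(
            f"state {lo} captures {occ[lo]:.3g} expected frames; "
            f"refit with a smaller K"
        )

    means = np.einsum("ntk,nt->k", gamma, x) / occ
    var = np.einsum("ntk,ntk->k", gamma, (x[:, :, None] - means[None, None, :]) ** 2) / occ
    var = np.maximum(var, var_floor)

    row = a_num.sum(axis=1, keepdims=True)
    transmat = np.where(row > 0, a_num / np.maximum(row, _TINY), 1.0 / model.k)
    startprob = gamma[:, 0, :].sum(axis=0)
    startprob = startprob / startprob.sum()

    new = HmmModel(means=means, variances=var, transmat=transmat, startprob=startprob)
    return new, loglik


def _transmat_stationary(transmat: np.ndarray) -> np.ndarray:
    k = len(transmat)
    a = np.vstack([transmat.T - np.eye(k), np.ones(k)])
    b = np.zeros(k + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(a, b, rcond=None)
    pi = np.clip(pi, 0, None)
    return pi / pi.sum()


def _split_state(model: HmmModel) -> HmmModel:
    """Split the state carrying the most occupancy-weighted variance.

    The chosen state's mean is moved +/- half its SD into two daughters
    that share its transition behavior; EM then separates them.  This
    deterministic hierarchical initialization resolves shoulder states
    (close-lying levels with very unequal occupancy) that a histogram-mode
    start misses.
    """
    pi = _transmat_stationary(model.transmat)
    i = int(np.argmax(pi * model.variances))
    k = model.k
    sd = float(np.sqrt(model.variances[i]))

    means = np.append(model.means, model.means[i] + 0.5 * sd)
    means[i] -= 0.5 * sd
    variances = np.append(model.variances, max(model.variances[i] / 2, _VAR_FLOOR))
    variances[i] = variances[-1]

    t = np.zeros((k + 1, k + 1))
    t[:k, :k] = model.transmat
    t[k, :k] = model.transmat[i]
    t[:k, k] = model.transmat[:, i] / 2
    t[:k, i] /= 2
    t[k, k] = model.transmat[i, i] / 2
    t[k, i] = model.transmat[i, i] / 2
    t[i, k] = t[i, i] / 2
    t[i, i] /= 2
    t /= t.sum(axis=1, keepdims=True)

    start = np.append(model.startprob, model.startprob[i] / 2)
    start[i] /= 2
    start /= start.sum()
    return HmmModel(means=means, variances=variances, transmat=t, startprob=start)


def _fit_em(x, mask, model: HmmModel, tol, max_iter, var_floor) -> HmmFit:
    history: list[float] = []
    converged = False
    ll_prev = -np.inf
    it = 0
    for it in range(1, max_iter + 1):
        model_new, ll = _em_step(x, mask, model, var_floor)
        history.append(ll)
        if np.isfinite(ll_prev) and ll - ll_prev <= tol * abs(ll_prev):
            converged = True
            # keep the parameters that produced ll (not the post-update ones)
            break
        model = model_new
        ll_prev = ll
    return HmmFit(
        model=model,
        log_likelihood=history[-1],
        history=history,
        converged=converged,
        n_iter=it,
    )


def fit_baum_welch(
    series,
    k: int,
    init: HmmModel | None = None,
    tol: float = 1e-6,
    max_iter: int = 500,
    var_floor: float = _VAR_FLOOR,
) -> HmmFit:
    """Fit a global K-state model to all valid segments jointly by EM.

    ``series`` is a sequence of :class:`EfretSeries` (or bare arrays with
    NaN marking invalid frames).  Without an explicit ``init`` the model is
    grown deterministically by hierarchical splitting: starting from the
    single-state closed form, the highest-variance state is split and the
    model refitted until K states exist.  The log-likelihood is
    non-decreasing at every EM iteration; each EM run stops at relative
    improvement below ``tol`` or at ``max_iter``.
    """
    values, _ = _collect(series)
    if not values:
        raise ValueError("no valid frames to fit")
    pooled = np.concatenate(values)
    if len(pooled) < 2 * k:
        raise ValueError(f"need at least {2 * k} valid frames to fit K={k}")
    x, mask = _pad(values)

    if init is not None:
        if init.k != k:
            raise ValueError(f"init model has K={init.k}, requested {k}")
        return _fit_em(x, mask, init, tol, max_iter, var_floor)

    model = HmmModel(
        means=np.array([float(np.mean(pooled))]),
        variances=np.array([max(float(np.var(pooled)), var_floor)]),
        transmat=np.array([[1.0]]),
        startprob=np.array([1.0]),
    )
    fit = _fit_em(x, mask, model, tol, max_iter, var_floor)
    for _ in range(2, k + 1):
        fit = _fit_em(x, mask, _split_state(fit.model), tol, max_iter, var_floor)
    return fit


def log_likelihood(model: HmmModel, series) -> float:
    """Total forward log-likelihood of ``series`` under ``model``."""
    values, _ = _collect(series)
    if not values:
        return 0.0
    x, mask = _pad(values)
    b = _emission_lik(x, mask, model)
    *_, ll = _forward_backward(b, mask, model)
    return ll


# ---------------------------------------------------------------------------
# Decoding
# ---------------------------------------------------------------------------


def _viterbi_batch(values: list[np.ndarray], model: HmmModel):
    """Most likely state sequence per segment; returns paths and logliks."""
    x, mask = _pad(values)
    n, t_max = x.shape
    k = model.k
    log_b = np.log(_emission_lik(x, mask, model))
    log_a = np.log(np.maximum(model.transmat, _TINY))
    log_start = np.log(np.maximum(model.startprob, _TINY))

    delta = log_start[None, :] + log_b[:, 0]
    psi = np.zeros((n, t_max, k), dtype=np.int32)
    psi[:, 0] = np.arange(k)[None, :]
    identity = np.arange(k)[None, :]
    for t in range(1, t_max):
        scores = delta[:, :, None] + log_a[None, :, :]  # (n, from, to)
        best_from = scores.argmax(axis=1)
        best_val = np.take_along_axis(scores, best_from[:, None, :], axis=1)[:, 0, :]
        new_delta = best_val + log_b[:, t]
        pad = ~mask[:, t]
        # padded steps: free self-transition, delta frozen
        psi[:, t] = np.where(pad[:, None], identity, best_from)
        delta = np.where(pad[:, None], delta, new_delta)

    states = np.zeros((n, t_max), dtype=np.int32)
    states[:, -1] = delta.argmax(axis=1)
    for t in range(t_max - 2, -1, -1):
        states[:, t] = np.take_along_axis(
            psi[:, t + 1], states[:, t + 1][:, None], axis=1
        )[:, 0]
    logliks = delta.max(axis=1)
    return [states[i, : len(values[i])] for i in range(n)], logliks


def viterbi_all(model: HmmModel, series: Sequence[EfretSeries]) -> list[IdealizedPath]:
    """Viterbi-decode a batch of series against a shared model."""
    values, prov = _collect(series)
    if values:
        seg_paths, seg_ll = _viterbi_batch(values, model)
    else:
        seg_paths, seg_ll = [], np.array([])

    out: list[IdealizedPath] = []
    for idx, e in enumerate(series):
        states = np.full(e.n_frames, -1, dtype=np.int32)
        ll = 0.0
        segments = []
        for (sidx, (eidx, lo, hi)) in enumerate(prov):
            if eidx != idx:
                continue
            states[lo:hi] = seg_paths[sidx]
            ll += float(seg_ll[sidx])
            segments.append((lo, hi))
        out.append(
            IdealizedPath(
                trace_id=e.trace_id,
                states=states,
                frame_period=e.frame_period,
                log_likelihood=ll,
                segments=segments,
            )
        )
    return out


def viterbi(model: HmmModel, e: EfretSeries) -> IdealizedPath:
    """Maximum-a-posteriori state sequence for one series.

    Invalid frames break the chain: each valid run is decoded independently,
    restarting from the initial distribution.  An all-invalid series yields
    an all ``-1`` path.
    """
    return viterbi_all(model, [e])[0]


def count_switches(path: IdealizedPath, lo: int = 0, hi: int | None = None) -> int:
    """Number of state changes between consecutive valid frames in [lo, hi)."""
    s = path.states[lo:hi]
    if len(s) < 2:
        return 0
    adjacent = (s[:-1] >= 0) & (s[1:] >= 0)
    return int(np.count_nonzero((np.diff(s) != 0) & adjacent))


# ---------------------------------------------------------------------------
# Model selection and labeling
# ---------------------------------------------------------------------------


def select_k(
    series,
    k_range: Sequence[int] = (1, 2, 3, 4),
    tol: float = 1e-6,
    max_iter: int = 500,
) -> int:
    """Choose the state count by BIC: -2 logL + p ln(n), p = K^2 + 2K - 1."""
    if not len(k_range):
        raise ValueError("k_range must be non-empty")
    values, _ = _collect(series)
    n_valid = int(sum(len(v) for v in values))
    best_k, best_bic = None, np.inf
    for k in sorted(k_range):
        try:
            fit = fit_baum_welch(series, k, tol=tol, max_iter=max_iter)
        except (DegenerateModelError, ValueError):
            continue
        bic = -2.0 * fit.log_likelihood + fit.model.n_parameters * np.log(n_valid)
        if bic < best_bic:
            best_k, best_bic = k, bic
    if best_k is None:
        raise DegenerateModelError("no K in range produced a non-degenerate fit")
    return best_k


def map_states_to_levels(
    model: HmmModel,
    canonical: dict[str, float] | None = None,
    tolerance: float = 0.08,
) -> dict[int, str]:
    """Label fitted states by the nearest canonical E level.

    States farther than ``tolerance`` from every canonical level are
    labeled ``"other"``.  Two states claiming the same canonical label
    within tolerance raise :class:`AmbiguousLabelError`.
    """
    if canonical is None:
        canonical = CANONICAL_LEVELS
    labels: dict[int, str] = {}
    claimed: dict[str, int] = {}
    for i, mu in enumerate(model.means):
        lab = min(canonical, key=lambda l: abs(canonical[l] - mu))
        if abs(canonical[lab] - mu) > tolerance:
            labels[i] = "other"
            continue
        if lab in claimed:
            raise AmbiguousLabelError(
                f"states {claimed[lab]} (mean {model.means[claimed[lab]]:.3f}) and "
                f"{i} (mean {mu:.3f}) both map to level {lab!r}"
            )
        claimed[lab] = i
        labels[i] = lab
    return labels
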