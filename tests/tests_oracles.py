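"""Shared independent oracles: exhaustive HMM path enumeration."""

import itertools

import numpy as np

from smfretkin.hmm import HmmModel
from smfretkin.preprocess import EfretSeries


def _gauss_loglik(v, model, s):
    var = model.variances[s]
    return -0.5 * ((v - model.means[s]) ** 2 / var + np.log(2 * np.pi * var))


def _path_logprob(model: HmmModel, x: np.ndarray, states) -> float:
    lp = np.log(model.startprob[states[0]]) + _gauss_loglik(x[0], model, states[0])
    for t in range(1, len(x)):
        lp += np.log(model.transmat[states[t - 1], states[t]])
        lp += _gauss_loglik(x[t], model, states[t])
    return lp


def brute_total_loglik(model: HmmModel, x: np.ndarray) -> float:
    lps = [
        _path_logprob(model, x, states)
        for states in itertools.product(range(model.k), repeat=len(x))
    ]
    m = max(lps)
    return m + np.log(sum(np.exp(lp - m) for lp in lps))


def brute_viterbi(model: HmmModel, x: np.ndarray) -> tuple:
    return max(
        itertools.product(range(model.k), repeat=len(x)),
        key=lambda states: _path_logprob(model, x, states),
    )


def random_model(rng, k: int) -> HmmModel:
    t = rng.uniform(0.1, 1.0, (k, k)) + 2 * np.eye(k)
    t /= t.sum(axis=1, keepdims=True)
    start = rng.uniform(0.2, 1.0, k)
    return HmmModel(
        means=np.sort(rng.uniform(0.0, 1.0, k)),
        variances=rng.uniform(0.002, 0.02, k),
        transmat=t,
        startprob=start / start.sum(),
    )


def make_series(x, trace_id="t"):
    x = np.asarray(x, float)
    return EfretSeries(
        trace_id=trace_id,
        E=x,
        valid=np.isfinite(x),
        frame_period=0.05,
        analysis_segments=[(0, len(x))] if np.isfinite(x).all() else [],
    )
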