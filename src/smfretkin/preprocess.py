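"""From raw two-channel traces to analyzable FRET-efficiency segments.

The apparent FRET efficiency (proximity ratio) of each frame is
``E = I_A / (I_A + I_D)``; no background, crosstalk, or gamma correction is
applied.  Frames are masked invalid where the denominator falls below a
floor (10% of the pre-bleach median total intensity by default, which
guards against 0/0 after photobleaching), inside the direct-acceptor-
excitation window, and at/after a detected donor bleach; frames after an
acceptor bleach carry no FRET information either.  E is deliberately not
clamped to [0, 1] — clamping would bias state means.

Photobleach detection is a running-median step detector: a donor bleach is
the first frame after which the smoothed total intensity stays below
``baseline_fraction`` times the pre-bleach level; an acceptor bleach is the
analogous single-channel drop accompanied by an anticorrelated donor rise.

Response classification compares the median E before and after buffer
injection against the canonical state levels and labels each molecule as
folding (N->F), extending (N->E), dynamic, static, or rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import median_filter

from .synth import CANONICAL_LEVELS
from .trace_io import Trace

__all__ = [
    "EfretSeries",
    "BleachCall",
    "ResponseCall",
    "MissingInjectionError",
    "compute_efret",
    "detect_bleach",
    "classify_response",
    "measure_delay",
    "fraction_percent",
]


class MissingInjectionError(ValueError):
    """Raised when a response call is requested without injection metadata.

    Traces without an injection time cannot be split into before/after
    segments; analyze them with the dynamics-only pipeline instead
    (idealize -> dwells -> rates).
    """


@dataclass
class EfretSeries:
    """Per-frame FRET efficiency with a validity mask and analysis segments.

    ``E`` is NaN wherever ``valid`` is False.  ``analysis_segments`` are the
    disjoint, ordered half-open frame ranges to analyze (pre- and
    post-injection when injection metadata exists, the whole usable trace
    otherwise).
    """

    trace_id: str
    E: np.ndarray
    valid: np.ndarray
    frame_period: float = 0.05
    injection_frame: int | None = None
    analysis_segments: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.E = np.asarray(self.E, float)
        self.valid = np.asarray(self.valid, bool)
        if self.E.shape != self.valid.shape:
            raise ValueError("E and valid must have the same shape")
        if np.any(~np.isfinite(self.E[self.valid])):
            raise ValueError("E must be finite wherever valid")
        prev_end = 0
        for s, e in self.analysis_segments:
            if not (prev_end <= s < e <= len(self.E)):
                raise ValueError(
                    f"analysis segments must be disjoint, ordered, in-bounds; "
                    f"got {self.analysis_segments}"
                )
            prev_end = e

    @property
    def n_frames(self) -> int:
        return len(self.E)

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    def valid_values(self) -> np.ndarray:
        return self.E[self.valid]


@dataclass(frozen=True)
class BleachCall:
    donor_bleach_frame: int | None = None
    acceptor_bleach_frame: int | None = None


@dataclass
class ResponseCall:
    """Classification of one molecule's reaction to buffer injection."""

    trace_id: str
    call: str  # fold | extend | static | dynamic | rejected
    pre_level: float = float("nan")
    post_level: float = float("nan")
    delay_s: float | None = None


def compute_efret(
    trace: Trace,
    bleach: BleachCall | None = None,
    denom_floor_frac: float = 0.10,
) -> EfretSeries:
    """Compute the proximity ratio series ``E = I_A / (I_A + I_D)``.

    Frames are masked where the total intensity is below
    ``denom_floor_frac`` of the pre-bleach median total, inside the
    direct-excitation window, and at/after either detected bleach.  A fully
    masked trace is allowed (its segments are empty).
    """
    total = trace.total
    n = trace.n_frames

    first_bleach = n
    if bleach is not None:
        for f in (bleach.donor_bleach_frame, bleach.acceptor_bleach_frame):
            if f is not None:
                first_bleach = min(first_bleach, f)

    pre = total[:first_bleach]
    floor = denom_floor_frac * (np.median(pre) if len(pre) else 0.0)

    valid = total > max(floor, 0.0)
    valid[first_bleach:] = False
    if trace.direct_excitation_window is not None:
        s, e = trace.direct_excitation_window
        valid[s:e] = False

    E = np.full(n, np.nan)
    E[valid] = trace.acceptor[valid] / total[valid]

    segments: list[tuple[int, int]] = []
    end = first_bleach
    if trace.injection_frame is not None and trace.injection_frame < end:
        if trace.injection_frame > 0:
            segments.append((0, trace.injection_frame))
        segments.append((trace.injection_frame, end))
    elif end > 0:
        segments.append((0, end))

    return EfretSeries(
        trace_id=trace.trace_id,
        E=E,
        valid=valid,
        frame_period=trace.frame_period,
        injection_frame=trace.injection_frame,
        analysis_segments=segments,
    )


def _first_persistent_below(
    smoothed: np.ndarray, reference: float, frac: float, persistence: int
) -> int | None:
    """First index from which ``smoothed`` stays below ``frac * reference``."""
    below = smoothed < frac * reference
    if not below.any():
        return None
    above = np.nonzero(~below)[0]
    start = int(above[-1]) + 1 if len(above) else 0
    if len(smoothed) - start < persistence:
        return None
    return start if below[start:].all() else None


def detect_bleach(
    trace: Trace, baseline_fraction: float = 0.25, persistence: int = 10
) -> BleachCall:
    """Detect donor and acceptor photobleach frames with a step detector.

    A donor bleach removes both channels (total intensity collapses); an
    acceptor bleach removes the acceptor while the donor, no longer
    quenched by energy transfer, rises to the full total intensity.  Traces
    shorter than the persistence window yield no call.
    """
    n = trace.n_frames
    if n < persistence:
        return BleachCall()
    win = min(max(3, persistence // 2) | 1, n)  # odd median window
    total_s = median_filter(trace.total, size=win, mode="nearest")
    acc_s = median_filter(trace.acceptor, size=win, mode="nearest")
    don_s = median_filter(trace.donor, size=win, mode="nearest")

    # the bright-phase level: median of frames near the upper range
    hi_ref = float(np.median(total_s[total_s >= 0.5 * np.percentile(total_s, 90)]))
    donor_bleach = _first_persistent_below(
        total_s, hi_ref, baseline_fraction, persistence
    )
    if donor_bleach == 0:
        donor_bleach = None  # dark from the start: nothing bleached on camera

    stop = donor_bleach if donor_bleach is not None else n
    acceptor_bleach = None
    if stop >= persistence:
        acc_ref = float(np.median(acc_s[:stop][acc_s[:stop] >= 0.5 * np.percentile(acc_s[:stop], 90)])) if np.any(acc_s[:stop] > 0) else 0.0
        cand = _first_persistent_below(
            acc_s[:stop], acc_ref, baseline_fraction, persistence
        )
        if cand is not None and cand > 0:
            # require the anticorrelated donor rise
            don_pre = float(np.median(don_s[:cand]))
            don_post = float(np.median(don_s[cand:stop]))
            if don_post > don_pre and don_post - don_pre > 0.5 * acc_ref * baseline_fraction:
                acceptor_bleach = cand
    return BleachCall(donor_bleach_frame=donor_bleach, acceptor_bleach_frame=acceptor_bleach)


def _nearest_level(value: float, levels: dict[str, float]) -> str:
    return min(levels, key=lambda lab: abs(levels[lab] - value))


def classify_response(
    e: EfretSeries,
    levels: dict[str, float] | None = None,
    pre_frames: int = 40,
    post_frames: int = 40,
    min_shift: float = 0.10,
    n_post_switches: int | None = None,
    persistence: int = 10,
) -> ResponseCall:
    """Classify a molecule's response to injection.

    ``pre_level`` is the median valid E over the ``pre_frames`` frames
    before injection; ``post_level`` over the last ``post_frames`` valid
    frames of the post segment (the tail, so delayed responders are judged
    by where they end up).  A call is ``fold`` when the post level sits
    nearest the folded level and rose by at least ``min_shift``; ``extend``
    when nearest the extended level and dropped by ``min_shift``;
    ``dynamic`` when the idealized post segment shows >= 2 level switches
    (pass the count via ``n_post_switches``); ``static`` otherwise;
    ``rejected`` when masking leaves too few frames on either side.
    """
    if levels is None:
        levels = CANONICAL_LEVELS
    if e.injection_frame is None:
        raise MissingInjectionError(
            f"trace {e.trace_id!r} has no injection_frame"
        )
    inj = e.injection_frame
    pre_window = e.E[max(0, inj - pre_frames) : inj]
    pre_vals = pre_window[np.isfinite(pre_window)]
    post_all = e.E[inj:]
    post_vals = post_all[np.isfinite(post_all)]
    if len(pre_vals) < max(2, pre_frames // 2) or len(post_vals) < max(2, post_frames // 2):
        return ResponseCall(trace_id=e.trace_id, call="rejected")

    pre_level = float(np.median(pre_vals))
    post_level = float(np.median(post_vals[-post_frames:]))

    nearest = _nearest_level(post_level, levels)
    call = "static"
    if nearest == "F" and post_level - pre_level >= min_shift:
        call = "fold"
    elif nearest == "E" and pre_level - post_level >= min_shift:
        call = "extend"
    elif n_post_switches is not None and n_post_switches >= 2:
        call = "dynamic"

    out = ResponseCall(
        trace_id=e.trace_id, call=call, pre_level=pre_level, post_level=post_level
    )
    if call in ("fold", "extend"):
        out.delay_s = measure_delay(
            e, call, levels=levels, min_shift=min_shift, persistence=persistence
        )
    return out


def measure_delay(
    e: EfretSeries,
    call: str,
    levels: dict[str, float] | None = None,
    min_shift: float = 0.10,
    persistence: int = 10,
) -> float:
    """Seconds from injection to the first sustained visit to the destination level.

    The destination is F for ``fold`` and E for ``extend`` calls.  The
    response onset is the first frame whose running-median E (window
    ``persistence`` frames) lies closer to the destination level than to
    the pre-injection level; a switch within one persistence window of the
    injection counts as immediate (delay 0).
    """
    if call not in ("fold", "extend"):
        raise ValueError(f"delay is defined for fold/extend calls, got {call!r}")
    if levels is None:
        levels = CANONICAL_LEVELS
    if e.injection_frame is None:
        raise MissingInjectionError(f"trace {e.trace_id!r} has no injection_frame")
    dest = levels["F"] if call == "fold" else levels["E"]
    src = levels["N"]

    inj = e.injection_frame
    post = e.E[inj:].copy()
    finite = np.isfinite(post)
    if not finite.any():
        return float("nan")
    # fill masked frames by the previous valid value so the median filter is defined
    idx = np.where(finite, np.arange(len(post)), -1)
    idx = np.maximum.accumulate(idx)
    post_filled = np.where(idx >= 0, post[np.maximum(idx, 0)], post[finite][0])
    med = median_filter(post_filled, size=max(3, persistence) | 1, mode="nearest")

    at_dest = np.abs(med - dest) < np.abs(med - src)
    win = min(max(persistence, 1), len(at_dest))
    sustained = np.convolve(at_dest.astype(int), np.ones(win, int), "valid") == win
    hits = np.nonzero(sustained)[0]
    if len(hits) == 0:
        return float("nan")
    first = int(hits[0])
    if first <= persistence:
        return 0.0
    return first * e.frame_period


def fraction_percent(n_selected: int, n_total: int) -> float:
    """Population fraction as a percentage, e.g. 752 of 1213 -> 62.0."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_selected <= n_total:
        raise ValueError("n_selected must lie in [0, n_total]")
    return 100.0 * n_selected / n_total
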