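"""Bead identification and dissociation-event calling from image stacks.

Mirrors the image-analysis stage of a centrifuge-force-microscope
experiment: circular features are detected in the first frame (circular
Hough transform), screened against rules that reject aggregated pairs,
noncircular debris, and out-of-range radii, and each accepted bead's pixel
intensity variance is tracked over a fixed disk at its first-frame
position (no re-centering: tether sway is part of the variance signal).
A dissociation event is the first sustained drop of the variance trace
from its bound level toward the unbound level; traces with more than one
distinct downward level shift are excluded as likely multiple tethers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter
from skimage.feature import canny
from skimage.transform import hough_circle, hough_circle_peaks

from stackpol.datatypes import ImageStack

STATUS_ACCEPTED = "accepted"


@dataclass(frozen=True)
class DetectionParams:
    """Circular-feature detection settings (radii in px).

    ``min_score`` thresholds the normalized Hough accumulator (fraction
    of the circle perimeter supported by edge pixels).
    """

    radius_range: tuple[int, int] = (3, 8)
    min_score: float = 0.45
    max_beads: int = 500
    canny_sigma: float = 2.0
    min_distance: float = 6.0


@dataclass(frozen=True)
class ScreeningCriteria:
    """Rules that demote detected candidates to excluded status."""

    min_separation: float = 12.0
    min_circularity: float = 0.85
    radius_range: tuple[float, float] = (2.0, 10.0)


@dataclass(frozen=True)
class CallParams:
    """Variance-drop event-calling settings (windows in frames)."""

    drop_fraction: float = 0.5
    persistence: int = 5
    smooth_window: int = 5
    baseline_window: int = 20
    tail_window: int = 20
    min_drop_rel: float = 0.25
    multistep_min_segment: int = 10
    multistep_gain: float = 0.25


@dataclass
class VarianceTrace:
    """Per-frame intensity variance within one bead's disk region."""

    bead_id: int
    values: np.ndarray
    times: np.ndarray

    def __post_init__(self) -> None:
        if (self.values < 0).any():
            raise ValueError("variance cannot be negative")
        if len(self.values) != len(self.times):
            raise ValueError("values/times length mismatch")


@dataclass
class EventCall:
    """Outcome of event calling for one bead."""

    bead_id: int
    outcome: str  # dissociated | censored | excluded_multistep
    time_s: float | None = None
    details: dict = field(default_factory=dict)


def circularity_score(frame: np.ndarray, x: float, y: float, radius: float
                      ) -> float:
    """Shape roundness of a candidate: |correlation| with an ideal disk.

    Pearson correlation magnitude between the local patch and a soft-edged
    disk template of the candidate radius; polarity-agnostic (dark or
    bright beads). Near 1 for round beads, low for elongated debris.
    Returns 0 for candidates whose window leaves the frame.
    """
    h, w = frame.shape
    r_win = int(np.ceil(radius)) + 2
    x0, x1 = int(round(x)) - r_win, int(round(x)) + r_win + 1
    y0, y1 = int(round(y)) - r_win, int(round(y)) + r_win + 1
    if x0 < 0 or y0 < 0 or x1 > w or y1 > h:
        return 0.0
    patch = frame[y0:y1, x0:x1].astype(float)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    rr = np.sqrt((xx - x) ** 2 + (yy - y) ** 2)
    template = np.clip(radius + 0.5 - rr, 0.0, 1.0)
    p = patch - patch.mean()
    t = template - template.mean()
    denom = np.sqrt((p * p).sum() * (t * t).sum())
    if denom == 0:
        return 0.0
    return float(abs((p * t).sum() / denom))


def detect_beads(frame: np.ndarray, params: DetectionParams | None = None
                 ) -> pd.DataFrame:
    """Detect circular features in a single grayscale frame.

    Circular Hough transform over the configured radius range, greedy
    non-maximum suppression across radii (``min_distance``), then a
    per-candidate :func:`circularity_score`. Returns a candidate table
    (columns ``x``, ``y``, ``radius``, ``hough_score``, ``score``,
    ``status='candidate'``), unscreened.
    """
    if params is None:
        params = DetectionParams()
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2 or min(frame.shape) < 8:
        raise ValueError("need a 2-D grayscale frame of reasonable size")
    if np.ptp(frame) == 0:
        return _empty_candidates()

    edges = canny(frame, sigma=params.canny_sigma)
    radii = np.arange(params.radius_range[0], params.radius_range[1] + 1)
    accum = hough_circle(edges, radii)
    scores, xs, ys, rs = hough_circle_peaks(
        accum, radii,
        total_num_peaks=params.max_beads * max(len(radii), 1),
        threshold=params.min_score,
    )
    if len(xs) == 0:
        return _empty_candidates()
    # the Hough accumulator separates poorly at small radii (few perimeter
    # pixels), so rank candidates by shape instead: score every admitted
    # peak by circularity, then greedy NMS across positions and radii
    circ_all = np.array([
        circularity_score(frame, float(x), float(y), float(r))
        for x, y, r in zip(xs, ys, rs)
    ])
    keep: list[int] = []
    min_d2 = params.min_distance**2
    for i in np.argsort(-circ_all):
        x, y = float(xs[i]), float(ys[i])
        if any((x - xs[j]) ** 2 + (y - ys[j]) ** 2 < min_d2 for j in keep):
            continue
        keep.append(i)
        if len(keep) >= params.max_beads:
            break

    df = pd.DataFrame({
        "bead_id": np.arange(len(keep)),
        "x": xs[keep].astype(float),
        "y": ys[keep].astype(float),
        "radius": rs[keep].astype(float),
        "hough_score": scores[keep].astype(float),
        "score": circ_all[keep],
        "status": "candidate",
    })
    return df


def _empty_candidates() -> pd.DataFrame:
    return pd.DataFrame(columns=["bead_id", "x", "y", "radius", "hough_score",
                                 "score", "status"])


def screen_beads(candidates: pd.DataFrame,
                 criteria: ScreeningCriteria | None = None) -> pd.DataFrame:
    """Apply exclusion rules; returns the table with ``status`` filled in.

    Rules, in order: ``excluded:low_circularity`` below the score
    threshold (such objects are not beads at all, so they do not
    participate in the pair rule); ``excluded:cluster`` for remaining
    pairs closer than ``min_separation`` (both members marked);
    ``excluded:radius_out_of_range``. Order-independent: the outcome does
    not depend on candidate row order.
    """
    if criteria is None:
        criteria = ScreeningCriteria()
    out = candidates.copy().reset_index(drop=True)
    if out.empty:
        return out
    status = np.array([STATUS_ACCEPTED] * len(out), dtype=object)

    low_circ = out["score"].to_numpy(dtype=float) < criteria.min_circularity
    status[low_circ] = "excluded:low_circularity"

    xy = out[["x", "y"]].to_numpy(dtype=float)
    d2 = ((xy[:, None, :] - xy[None, :, :]) ** 2).sum(axis=2)
    np.fill_diagonal(d2, np.inf)
    d2[low_circ, :] = np.inf
    d2[:, low_circ] = np.inf
    clustered = (d2 < criteria.min_separation**2).any(axis=1)
    status[clustered & ~low_circ] = "excluded:cluster"

    r = out["radius"].to_numpy(dtype=float)
    bad_r = (r < criteria.radius_range[0]) | (r > criteria.radius_range[1])
    status[(status == STATUS_ACCEPTED) & bad_r] = "excluded:radius_out_of_range"

    out["status"] = status
    return out


def disk_mask(shape: tuple[int, int], x: float, y: float, radius: float
              ) -> np.ndarray:
    """Boolean mask of the disk of ``radius`` centered at (x, y)."""
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    return (xx - x) ** 2 + (yy - y) ** 2 <= radius**2


def variance_trace(stack: ImageStack, x: float, y: float, radius: float,
                   bead_id: int = 0) -> VarianceTrace:
    """Unbiased per-frame intensity variance over a fixed disk region.

    The disk is centered at the bead's first-frame position for the whole
    movie. Raises if the disk extends outside the frame (such beads are
    excluded upstream with reason ``edge``).
    """
    h, w = stack.shape
    if (x - radius < 0 or y - radius < 0 or x + radius > w - 1
            or y + radius > h - 1):
        raise ValueError("disk partially outside frame")
    mask = disk_mask((h, w), x, y, radius)
    region = stack.frames[:, mask].astype(float)
    values = region.var(axis=1, ddof=1)
    return VarianceTrace(bead_id=bead_id, values=values,
                         times=stack.frame_times())


def _segment_means(trace: np.ndarray, min_segment: int, gain: float
                   ) -> list[float]:
    """Greedy binary segmentation into piecewise-constant levels.

    A split is accepted while it removes at least ``gain`` of the parent
    segment's sum of squared residuals. Returns the per-segment means in
    time order.
    """
    def best_split(seg: np.ndarray) -> tuple[int | None, float]:
        n = len(seg)
        if n < 2 * min_segment:
            return None, 0.0
        csum = np.cumsum(seg)
        csq = np.cumsum(seg**2)
        total = csq[-1] - csum[-1] ** 2 / n
        best_i, best_red = None, 0.0
        for i in range(min_segment, n - min_segment + 1):
            left_ss = csq[i - 1] - csum[i - 1] ** 2 / i
            rn = n - i
            rsum = csum[-1] - csum[i - 1]
            right_ss = (csq[-1] - csq[i - 1]) - rsum**2 / rn
            red = total - left_ss - right_ss
            if red > best_red:
                best_i, best_red = i, red
        if total <= 0 or best_i is None or best_red < gain * total:
            return None, 0.0
        return best_i, best_red

    segments: list[np.ndarray] = []

    def recurse(seg: np.ndarray, depth: int) -> None:
        i, _ = best_split(seg) if depth < 6 else (None, 0.0)
        if i is None:
            segments.append(seg)
        else:
            recurse(seg[:i], depth + 1)
            recurse(seg[i:], depth + 1)

    recurse(trace, 0)
    return [float(s.mean()) for s in segments]


def call_dissociation(trace: VarianceTrace, time_zero: float,
                      params: CallParams | None = None) -> EventCall:
    """Call the dissociation time from one variance trace.

    The bound level B and unbound level U are two-level sliding-median
    estimates: the trace is median-smoothed, split at the midpoint of its
    range, and B/U are the medians of the upper and lower halves. (Unlike a fixed initial-window B, this stays correct for
    beads that dissociate early in the run.) The event is the first frame
    where the smoothed trace crosses below
    ``B - drop_fraction * (B - U)`` and stays below for ``persistence``
    frames; no crossing (or no meaningful drop) gives ``censored``. More
    than one distinct downward level shift gives ``excluded_multistep``.
    """
    if params is None:
        params = CallParams()
    times = trace.times
    t0_candidates = np.flatnonzero(times >= time_zero)
    if t0_candidates.size == 0:
        raise ValueError("trace does not cover time_zero")
    i0 = int(t0_candidates[0])
    v = np.asarray(trace.values, dtype=float)[i0:]
    t = times[i0:]
    needed = max(params.baseline_window + params.tail_window,
                 2 * params.persistence)
    if len(v) < needed:
        raise ValueError("trace shorter than analysis windows")

    smooth = median_filter(v, size=params.smooth_window, mode="nearest")
    # min/max of the already-median-smoothed trace: robust to single-frame
    # spikes yet valid even when one level occupies a small trace fraction
    mid = 0.5 * (float(smooth.min()) + float(smooth.max()))
    upper = smooth[smooth >= mid]
    lower = smooth[smooth < mid]
    bound = float(np.median(upper)) if upper.size else float(np.median(smooth))
    unbound = float(np.median(lower)) if lower.size else bound

    drop = bound - unbound
    if bound <= 0 or drop < params.min_drop_rel * bound:
        return EventCall(trace.bead_id, "censored",
                         details={"bound": bound, "unbound": unbound})

    # multistep check on the level structure of the whole trace
    levels = _segment_means(smooth, params.multistep_min_segment,
                            params.multistep_gain)
    down_steps = sum(
        1 for a, b in zip(levels[:-1], levels[1:])
        if a - b > params.min_drop_rel * drop
    )
    if down_steps > 1:
        return EventCall(trace.bead_id, "excluded_multistep",
                         details={"levels": levels})

    threshold = bound - params.drop_fraction * drop
    below = smooth < threshold
    # first index from which the trace stays below for `persistence` frames
    run = 0
    event_idx = None
    for i, flag in enumerate(below):
        run = run + 1 if flag else 0
        if run >= params.persistence:
            event_idx = i - params.persistence + 1
            break
    if event_idx is None:
        return EventCall(trace.bead_id, "censored",
                         details={"bound": bound, "unbound": unbound})
    return EventCall(
        trace.bead_id, "dissociated",
        time_s=float(t[event_idx] - time_zero),
        details={"bound": bound, "unbound": unbound, "threshold": threshold},
    )


def track_stack(
    stack: ImageStack,
    detection: DetectionParams | None = None,
    screening: ScreeningCriteria | None = None,
    calling: CallParams | None = None,
    time_zero: float | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Full tracking pipeline: detect, screen, trace, call.

    Returns ``(events, qc)``: one row per detected bead with columns
    ``bead_id, x, y, radius, outcome, time_s, reason``, and a QC dict of
    counts per stage/exclusion reason.
    """
    if time_zero is None:
        time_zero = stack.time_zero
    candidates = detect_beads(stack.frames[0], detection)
    screened = screen_beads(candidates, screening)

    rows = []
    qc: dict[str, int] = {"detected": len(screened)}
    for row in screened.itertuples():
        if row.status != STATUS_ACCEPTED:
            reason = row.status.split(":", 1)[1]
            qc[f"excluded_{reason}"] = qc.get(f"excluded_{reason}", 0) + 1
            rows.append((row.bead_id, row.x, row.y, row.radius,
                         "excluded", None, reason))
            continue
        try:
            tr = variance_trace(stack, row.x, row.y, row.radius, row.bead_id)
        except ValueError:
            qc["excluded_edge"] = qc.get("excluded_edge", 0) + 1
            rows.append((row.bead_id, row.x, row.y, row.radius,
                         "excluded", None, "edge"))
            continue
        call = call_dissociation(tr, time_zero, calling)
        qc[call.outcome] = qc.get(call.outcome, 0) + 1
        rows.append((row.bead_id, row.x, row.y, row.radius,
                     call.outcome, call.time_s, ""))

    events = pd.DataFrame(
        rows, columns=["bead_id", "x", "y", "radius", "outcome", "time_s",
                       "reason"]
    )
    return events, qc
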