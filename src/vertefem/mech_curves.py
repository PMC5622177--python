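"""Apparent stiffness from load-displacement records.

The experimental apparent stiffness of a compressed specimen is taken as the
largest slope found by a moving window of fixed displacement aperture
(default 0.6 mm) slid along the curve; within each window the slope is the
ordinary-least-squares fit of load against displacement.  This picks out the
steepest quasi-linear region between the toe and the post-yield plateau and
is robust to sample noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_WINDOW_MM = 0.6


@dataclass
class LoadDisplacementCurve:
    """A compression test record: displacement (mm, strictly increasing)
    against load (kN)."""

    displacement: np.ndarray
    load: np.ndarray
    specimen_id: str = ""

    def __post_init__(self):
        self.displacement = np.asarray(self.displacement, dtype=float)
        self.load = np.asarray(self.load, dtype=float)
        if self.displacement.shape != self.load.shape or self.displacement.ndim != 1:
            raise ValueError("displacement and load must be equal-length 1-D arrays")
        if self.displacement.size < 2:
            raise ValueError("curve needs at least 2 samples")
        diffs = np.diff(self.displacement)
        if np.any(diffs <= 0):
            # tolerate sub-micron machine reversals by re-sorting; anything
            # larger is a corrupt record
            if np.all(diffs > -1e-3):
                order = np.argsort(self.displacement, kind="stable")
                self.displacement = self.displacement[order]
                self.load = self.load[order]
                keep = np.concatenate([[True], np.diff(self.displacement) > 0])
                self.displacement = self.displacement[keep]
                self.load = self.load[keep]
            else:
                raise ValueError("displacement not strictly increasing (reversal > 1 um)")

    @property
    def span(self) -> float:
        return float(self.displacement[-1] - self.displacement[0])


@dataclass
class StiffnessEstimate:
    stiffness: float  # kN/mm
    window_width: float = DEFAULT_WINDOW_MM  # mm
    window_center: float = 0.0  # mm

    def __post_init__(self):
        if not np.isfinite(self.stiffness):
            raise ValueError("stiffness must be finite")


def _ols_slopes(d: np.ndarray, p: np.ndarray, starts: np.ndarray, stops: np.ndarray) -> np.ndarray:
    """OLS slope of p vs d over each half-open sample range [start, stop),
    computed with prefix sums so the sweep is O(n)."""
    one = np.concatenate([[0.0], np.cumsum(np.ones_like(d))])
    sd = np.concatenate([[0.0], np.cumsum(d)])
    sp = np.concatenate([[0.0], np.cumsum(p)])
    sdd = np.concatenate([[0.0], np.cumsum(d * d)])
    sdp = np.concatenate([[0.0], np.cumsum(d * p)])
    n = one[stops] - one[starts]
    sum_d = sd[stops] - sd[starts]
    sum_p = sp[stops] - sp[starts]
    sum_dd = sdd[stops] - sdd[starts]
    sum_dp = sdp[stops] - sdp[starts]
    denom = n * sum_dd - sum_d**2
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = (n * sum_dp - sum_d * sum_p) / denom
    slope[denom <= 0] = np.nan
    return slope


def extract_stiffness(curve: LoadDisplacementCurve, window_width: float = DEFAULT_WINDOW_MM) -> StiffnessEstimate:
    """Largest moving-window OLS slope of the load-displacement curve.

    Windows step one sample at a time; only windows whose displacement
    aperture fits entirely inside the record are considered, and windows
    with fewer than 3 samples are skipped.

    Returns the maximal slope (kN/mm) and the centre of the window where it
    was found.
    """
    if window_width <= 0:
        raise ValueError("window_width must be positive")
    d, p = curve.displacement, curve.load
    if curve.span < window_width - 1e-12:
        raise ValueError(
            f"curve span {curve.span:.3f} mm is shorter than the {window_width} mm window"
        )
    # window starting at sample i covers samples with d in [d_i, d_i + w]
    starts = np.flatnonzero(d <= d[-1] - window_width + 1e-12)
    stops = np.searchsorted(d, d[starts] + window_width + 1e-12, side="right")
    valid = (stops - starts) >= 3
    starts, stops = starts[valid], stops[valid]
    if starts.size == 0:
        raise ValueError("no window contains at least 3 samples")
    slopes = _ols_slopes(d, p, starts, stops)
    if np.all(np.isnan(slopes)):
        raise ValueError("no valid window (all windows degenerate)")
    best = int(np.nanargmax(slopes))
    center = 0.5 * (d[starts[best]] + d[stops[best] - 1])
    return StiffnessEstimate(
        stiffness=float(slopes[best]),
        window_width=float(window_width),
        window_center=float(center),
    )
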