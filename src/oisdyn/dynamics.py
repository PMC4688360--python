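"""Per-region intensity and diameter dynamics.

Diameter changes are quantified by pixel counting: within a small
morphological dilation of the responsive-artery region, pixels darker than
a baseline-calibrated vessel/tissue boundary count as vessel; the trace is
the percent change of that count vs. its pre-stimulus mean. Intensity and
dilation traces are binned in non-overlapping 3-frame bins (0.3 s at
10 Hz), and each trace is summarized by max change, time-to-peak, onset
(baseline mean + 2 SD crossing) and rising slope.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import disk

from .cbv import DynamicsMetrics, ResponseMovie
from .io import OISMovie

__all__ = [
    "RegionTrace",
    "bin_by_three",
    "bin_center_times",
    "make_region_trace",
    "intensity_trace",
    "dilation_trace",
    "onset_time",
    "rising_slope",
    "normalize_trace_to_100",
    "peak_metrics",
]

BIN_FRAMES = 3
#: floor on the baseline SD (trace units) so zero-noise traces still define
#: an onset threshold
BASELINE_SD_EPS = 1e-6


@dataclass
class RegionTrace:
    """A 3-frame-binned response trace for one region.

    values are percent change vs. baseline (intensity traces) or percent
    pixel-count change vs. baseline (dilation traces); times are bin
    centers in seconds from recording start.
    """

    values: np.ndarray
    bin_times_s: np.ndarray
    bin_duration_s: float
    baseline_mean: float
    baseline_sd: float
    stim_onset_s: float
    region_name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.bin_times_s = np.asarray(self.bin_times_s, dtype=float)
        if self.values.shape != self.bin_times_s.shape:
            raise ValueError("values and bin_times_s must align")
        if self.baseline_sd < 0:
            raise ValueError("baseline_sd must be >= 0")

    @property
    def n_bins(self) -> int:
        return self.values.size

    def post_onset_indices(self) -> np.ndarray:
        return np.flatnonzero(self.bin_times_s >= self.stim_onset_s)


def bin_by_three(series: np.ndarray) -> np.ndarray:
    """Non-overlapping consecutive 3-frame means; a final partial bin is
    averaged over its actual length."""
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise ValueError("empty series")
    n_bins = -(-series.size // BIN_FRAMES)  # ceil
    out = np.empty(n_bins)
    for b in range(n_bins):
        out[b] = series[b * BIN_FRAMES : (b + 1) * BIN_FRAMES].mean()
    return out


def bin_center_times(n_frames: int, frame_rate_hz: float) -> np.ndarray:
    """Center time of each 3-frame bin (partial final bin uses its own span)."""
    t = np.arange(n_frames) / frame_rate_hz
    n_bins = -(-n_frames // BIN_FRAMES)
    return np.array(
        [t[b * BIN_FRAMES : (b + 1) * BIN_FRAMES].mean() for b in range(n_bins)]
    )


def make_region_trace(
    per_frame: np.ndarray,
    frame_rate_hz: float,
    stim_onset_s: float,
    region_name: str = "",
) -> RegionTrace:
    """Bin a per-frame series and attach baseline statistics.

    Baseline bins are those lying entirely before stimulation onset; at
    least 3 are required.
    """
    per_frame = np.asarray(per_frame, dtype=float)
    values = bin_by_three(per_frame)
    times = bin_center_times(per_frame.size, frame_rate_hz)
    # a bin is baseline if its last frame precedes the stimulus
    last_frame_time = (
        np.minimum(np.arange(values.size) * BIN_FRAMES + BIN_FRAMES - 1, per_frame.size - 1)
        / frame_rate_hz
    )
    base = values[last_frame_time < stim_onset_s]
    if base.size < 3:
        raise ValueError("need at least 3 pre-stimulus bins for baseline statistics")
    return RegionTrace(
        values=values,
        bin_times_s=times,
        bin_duration_s=BIN_FRAMES / frame_rate_hz,
        baseline_mean=float(base.mean()),
        baseline_sd=float(base.std(ddof=0)),
        stim_onset_s=stim_onset_s,
        region_name=region_name,
    )


def intensity_trace(
    response: ResponseMovie, region: np.ndarray, region_name: str = ""
) -> RegionTrace:
    """Binned mean percent change over the region's pixels."""
    region = np.asarray(region, dtype=bool)
    if not region.any():
        raise ValueError("empty region")
    per_frame = response.pct_change[:, region].mean(axis=1)
    return make_region_trace(
        per_frame, response.frame_rate_hz, response.stim_onset_s, region_name
    )


def dilation_trace(
    movie: OISMovie,
    artery_region: np.ndarray,
    exclude: np.ndarray | None = None,
    dilate_px: int = 3,
    region_name: str = "responsive_pial_artery",
) -> RegionTrace:
    """Pixel-count diameter trace for the selected artery region.

    The search neighborhood is a ``dilate_px``-radius morphological dilation
    of the region (so widening vessels stay inside it); an ``exclude`` mask
    (typically the other vessels in the field, e.g. the non-responsive
    ones) is removed from the neighborhood together with a 1-px rim, so
    their blurred edges cannot leak into the count. The vessel/tissue
    decision boundary is Otsu's threshold on the baseline-mean image within
    the neighborhood; per frame, pixels darker than the boundary count as
    vessel, and the trace is the percent change of the count vs. its
    pre-stimulus mean, 3-frame binned.
    """
    artery_region = np.asarray(artery_region, dtype=bool)
    if not artery_region.any():
        raise ValueError("empty artery region")
    nbhd = ndimage.binary_dilation(artery_region, structure=disk(dilate_px))
    if exclude is not None:
        rim = ndimage.binary_dilation(np.asarray(exclude, dtype=bool), structure=disk(1))
        nbhd &= ~rim
        if not nbhd.any():
            raise ValueError("exclusion mask removed the whole neighborhood")
    baseline_img = movie.frames[: movie.n_baseline_frames].mean(axis=0)
    boundary = threshold_otsu(baseline_img[nbhd])
    counts = (movie.frames[:, nbhd] < boundary).sum(axis=1).astype(float)
    base_count = counts[: movie.n_baseline_frames].mean()
    if base_count == 0:
        raise ValueError("no vessel pixels at baseline under the intensity criterion")
    per_frame = 100.0 * (counts / base_count - 1.0)
    return make_region_trace(
        per_frame, movie.frame_rate_hz, movie.stim_onset_s, region_name
    )


def onset_time(trace: RegionTrace) -> float | None:
    """First post-stimulus bin exceeding baseline mean + 2 baseline SD.

    Returns bin-center time in seconds from stimulation onset, or ``None``
    if the trace never crosses the threshold.
    """
    thr = trace.baseline_mean + 2.0 * max(trace.baseline_sd, BASELINE_SD_EPS)
    for i in trace.post_onset_indices():
        if trace.values[i] > thr:
            return float(trace.bin_times_s[i] - trace.stim_onset_s)
    return None


def _peak_bin(trace: RegionTrace) -> int:
    idx = trace.post_onset_indices()
    if idx.size == 0:
        raise ValueError("no bins at/after stimulation onset")
    return int(idx[np.argmax(trace.values[idx])])


def rising_slope(trace: RegionTrace, onset_s: float, peak_bin: int | None = None) -> float:
    """(peak value - onset-bin value) / (peak time - onset time), %/s."""
    if peak_bin is None:
        peak_bin = _peak_bin(trace)
    onset_abs = onset_s + trace.stim_onset_s
    onset_idx = int(np.argmin(np.abs(trace.bin_times_s - onset_abs)))
    peak_t = trace.bin_times_s[peak_bin]
    if peak_t <= trace.bin_times_s[onset_idx]:
        raise ValueError("peak must come after onset")
    return float(
        (trace.values[peak_bin] - trace.values[onset_idx])
        / (peak_t - trace.bin_times_s[onset_idx])
    )


def normalize_trace_to_100(trace: RegionTrace) -> RegionTrace:
    """Scale so the trace maximum is exactly 100 (timing is unchanged)."""
    m = trace.values.max()
    if m <= 0:
        raise ValueError("trace maximum must be positive to normalize")
    f = 100.0 / m
    return replace(
        trace,
        values=trace.values * f,
        baseline_mean=trace.baseline_mean * f,
        baseline_sd=trace.baseline_sd * f,
    )


def peak_metrics(trace: RegionTrace) -> DynamicsMetrics:
    """Max change, time-to-peak, onset and rising slope for one trace.

    The peak search is restricted to bins from stimulation onset onward;
    onset and slope are ``None`` when the trace never leaves baseline.
    """
    pk = _peak_bin(trace)
    ttp = float(trace.bin_times_s[pk] - trace.stim_onset_s)
    onset = onset_time(trace)
    slope = None
    if onset is not None:
        try:
            slope = rising_slope(trace, onset, pk)
        except ValueError:
            slope = None
    return DynamicsMetrics(
        max_change_pct=float(trace.values[pk]),
        time_to_peak_s=ttp,
        onset_time_s=onset,
        rising_slope_pct_per_s=slope,
    )
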