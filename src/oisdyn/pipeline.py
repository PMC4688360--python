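"""End-to-end per-animal analyses composed from the step modules.

These helpers run the standard chains — trials -> averaged/filtered movie
-> response movie -> ROI metrics, and movie -> segmentation -> SD-map
regions -> dilation metrics — so drivers, the CLI and batch cohort
analyses share one code path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import cbv, dynamics, regions, segmentation
from .cbv import DynamicsMetrics, ResponseMovie, RoiSelection
from .io import OISMovie, TrialSet
from .regions import RegionMasks
from .synthetic import Cohort, GroundTruth

__all__ = [
    "CbvResult",
    "VascularResult",
    "preprocess_trials",
    "analyze_cbv",
    "segment_from_truth",
    "analyze_vascular",
    "cohort_cbv_table",
]


@dataclass
class CbvResult:
    response: ResponseMovie
    roi: RoiSelection
    trace: np.ndarray
    metrics: DynamicsMetrics
    extent_mm2: np.ndarray  # per-frame activated area


@dataclass
class VascularResult:
    region_masks: RegionMasks
    dilation_metrics: DynamicsMetrics
    nonresponsive_metrics: DynamicsMetrics | None
    dilation_trace: dynamics.RegionTrace
    vessel_iou: float | None = None  # vs. ground truth, when known


def preprocess_trials(
    trials: TrialSet, cutoff_hz: float = cbv.DEFAULT_CUTOFF_HZ
) -> OISMovie:
    """Trial averaging followed by zero-phase temporal low-pass filtering."""
    return cbv.lowpass_filter(cbv.average_trials(trials), cutoff_hz)


def analyze_cbv(
    trials: TrialSet,
    cutoff_hz: float = cbv.DEFAULT_CUTOFF_HZ,
    crop_center: tuple[int, int] | None = None,
    side_mm: float = 3.0,
    roi_size: int = 7,
    threshold_pct: float = 1.0,
    sign: str = "reflectance",
) -> CbvResult:
    """Average, filter, normalize, crop, pick the ROI and summarize it.

    ``crop_center`` defaults to the field center; pass ``side_mm=None`` to
    skip cropping.
    """
    movie = preprocess_trials(trials, cutoff_hz)
    response = cbv.normalize_to_baseline(movie, sign=sign)
    if side_mm is not None:
        _, h, w = response.pct_change.shape
        if crop_center is None:
            crop_center = (h // 2, w // 2)
        response = cbv.crop_to_window(response, crop_center[0], crop_center[1], side_mm)
    roi = cbv.select_roi(response, size=roi_size)
    trace = cbv.roi_trace(response, roi)
    metrics = cbv.max_cbv_and_ttp(trace, response.frame_rate_hz, response.stim_onset_s)
    extent = cbv.activation_extent(response, threshold_pct)
    return CbvResult(response=response, roi=roi, trace=trace, metrics=metrics, extent_mm2=extent)


def segment_from_truth(
    baseline_image: np.ndarray,
    truth_vessel_mask: np.ndarray,
    rng_seed: int = 0,
    n_scribbles: int = 800,
) -> segmentation.VesselProbabilityMap:
    """Train the pixel classifier from auto-scribbles off a known mask."""
    labels = segmentation.auto_scribbles(
        truth_vessel_mask, n_per_class=n_scribbles, rng=rng_seed
    )
    feats = segmentation.extract_pixel_features(baseline_image)
    clf = segmentation.train_classifier(feats, labels, rng_seed=rng_seed)
    return segmentation.predict_probability(clf, baseline_image)


def analyze_vascular(
    trials: TrialSet,
    truth: GroundTruth | None = None,
    prob_map: segmentation.VesselProbabilityMap | None = None,
    cutoff_hz: float = cbv.DEFAULT_CUTOFF_HZ,
    vessel_threshold: float = 0.6,
    rng_seed: int = 0,
) -> VascularResult:
    """Segmentation + SD-map region decomposition + dilation dynamics.

    The classifier is trained on the baseline-mean image; scribbles come
    from the supplied ground truth unless a probability map is given
    directly (user-trained route).
    """
    movie = preprocess_trials(trials, cutoff_hz)
    baseline_img = movie.frames[: movie.n_baseline_frames].mean(axis=0)
    if prob_map is None:
        if truth is None:
            raise ValueError("need either a ground truth or a probability map")
        prob_map = segment_from_truth(baseline_img, truth.vessel_mask, rng_seed)
    sdmap = regions.smooth_map(regions.compute_sd_map(movie))
    responsive = regions.responsive_mask(sdmap)
    masks = regions.decompose_regions(responsive, prob_map, vessel_threshold)

    # the counting denominator must span the artery's full cross-section, so
    # only vessel components unrelated to the responsive artery are excluded
    # (the SD map tends to mark the dilating edges, leaving the interior
    # labelled "non-responsive")
    from scipy import ndimage

    vessel = prob_map.prob > vessel_threshold
    lab, _ = ndimage.label(vessel)
    keep = np.unique(lab[masks.responsive_pial_artery])
    related = np.isin(lab, keep[keep > 0])
    unrelated_vessels = vessel & ~related
    trace = dynamics.dilation_trace(
        movie, masks.responsive_pial_artery, exclude=unrelated_vessels
    )
    dil_metrics = dynamics.peak_metrics(trace)

    nonresp_metrics = None
    if masks.nonresponsive_vessels.any():
        nr_trace = dynamics.dilation_trace(
            movie,
            masks.nonresponsive_vessels,
            exclude=masks.responsive_pial_artery,
            region_name="nonresponsive_vessels",
        )
        nonresp_metrics = dynamics.peak_metrics(nr_trace)

    iou = None
    if truth is not None:
        pred = segmentation.threshold_vessels(prob_map, vessel_threshold)
        inter = (pred & truth.vessel_mask).sum()
        union = (pred | truth.vessel_mask).sum()
        iou = float(inter / union) if union else 0.0
    return VascularResult(
        region_masks=masks,
        dilation_metrics=dil_metrics,
        nonresponsive_metrics=nonresp_metrics,
        dilation_trace=trace,
        vessel_iou=iou,
    )


def cohort_cbv_table(
    cohort: Cohort, cutoff_hz: float = cbv.DEFAULT_CUTOFF_HZ, **kwargs
) -> pd.DataFrame:
    """Per-animal CBV metrics for a synthetic cohort (rendered lazily)."""
    rows = []
    for spec, _truth, trials in cohort.iter_rendered():
        res = analyze_cbv(trials, cutoff_hz=cutoff_hz, **kwargs)
        rows.append(
            {
                "animal": spec.animal_id,
                "group": spec.group,
                "max_cbv_pct": res.metrics.max_change_pct,
                "time_to_peak_s": res.metrics.time_to_peak_s,
                "injected_amplitude_pct": spec.params.peak_amplitude_pct,
                "injected_ttp_s": spec.params.time_to_peak_s,
            }
        )
    return pd.DataFrame(rows)
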