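"""Synthetic optical-intrinsic-signal (OIS) movie generator with ground truth.

Emulates 570 nm reflectance recordings of a cortical field of view: dark
branching pial vessels on brighter parenchyma, a stimulus-locked localized
reflectance *decrease* (CBV increase) with a gamma-variate time course,
stimulus-locked widening of the arteries inside the responsive footprint,
plus additive white noise and global sinusoidal physiological oscillations.

The default protocol is 8 trials of 200 frames at 10 Hz with a 5-s stimulus
starting 5 s into each trial. Default effect sizes correspond to a healthy
("control") animal: 4.02% peak CBV change peaking 4.65 s after stimulus
onset and 6.48% peak artery dilation; the "stress" condition uses 1.82%,
5.43 s and 3.49%.

Geometry is held as centerline segments with widths. Each pixel stores its
*normalized* distance to the nearest segment (distance divided by the
segment's rest half-width), so rasterizing the tree at any width scale `s`
is the comparison ``norm_dist <= s`` — exact per-frame dilation at no cost.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io import OISMovie, TrialSet

__all__ = [
    "ScenarioParams",
    "VesselSegment",
    "GroundTruth",
    "CONTROL_PARAMS",
    "STRESS_PARAMS",
    "CONTROL_BETWEEN_ANIMAL_SD",
    "STRESS_BETWEEN_ANIMAL_SD",
    "generate_vessel_tree",
    "render_trials",
    "rasterize_at_scale",
    "generate_cohort",
    "Cohort",
    "save_scenario",
]


@dataclass(frozen=True)
class ScenarioParams:
    """Configuration of one synthetic animal / stimulation session.

    Amplitudes are percent of baseline intensity; times are seconds.
    """

    image_height_px: int = 128
    image_width_px: int = 128
    pixel_size_mm: float = 0.04
    n_frames: int = 200
    frame_rate_hz: float = 10.0
    stim_onset_s: float = 5.0
    stim_duration_s: float = 5.0
    n_trials: int = 8
    peak_amplitude_pct: float = 4.02
    time_to_peak_s: float = 4.65
    dilation_pct: float = 6.48
    footprint_radius_mm: float = 1.0
    noise_sd_pct: float = 0.2
    osc_components: tuple[tuple[float, float], ...] = ((1.0, 0.2), (4.0, 0.1))
    rng_seed: int = 0
    # renderer constants: vessels are `vessel_contrast` darker than tissue,
    # tissue baseline sits at `baseline_counts` camera counts, and the
    # optics blur the scene by `blur_sigma_px` (the ground-truth vessel
    # mask stays the unblurred raster)
    vessel_contrast: float = 0.4
    baseline_counts: float = 4000.0
    blur_sigma_px: float = 1.0
    vessel_width_scale: float = 1.0
    kernel_shape: float = 3.0

    def validate(self) -> None:
        if self.image_height_px < 32 or self.image_width_px < 32:
            raise ValueError("image too small: both dimensions must be >= 32 px")
        if self.n_frames / self.frame_rate_hz <= self.stim_onset_s + self.stim_duration_s:
            raise ValueError("recording must outlast stimulation")
        if self.peak_amplitude_pct < 0 or self.dilation_pct < 0:
            raise ValueError("amplitudes must be non-negative")
        if self.pixel_size_mm <= 0 or self.frame_rate_hz <= 0:
            raise ValueError("pixel size and frame rate must be positive")

    @property
    def n_baseline_frames(self) -> int:
        return int(round(self.stim_onset_s * self.frame_rate_hz))

    @property
    def footprint_radius_px(self) -> float:
        return self.footprint_radius_mm / self.pixel_size_mm


#: Study-condition defaults for the two groups (healthy vs chronic stress).
CONTROL_PARAMS = ScenarioParams()
STRESS_PARAMS = replace(
    CONTROL_PARAMS, peak_amplitude_pct=1.82, time_to_peak_s=5.43, dilation_pct=3.49
)

#: Between-animal SDs for cohort sampling, from printed SEMs via SD = SEM*sqrt(n)
#: (max dCBV and TTP: n=10 per group; dilation: n=6 control, n=5 stress).
CONTROL_BETWEEN_ANIMAL_SD = {
    "peak_amplitude_pct": 0.34 * math.sqrt(10),
    "time_to_peak_s": 0.25 * math.sqrt(10),
    "dilation_pct": 2.38 * math.sqrt(6),
}
STRESS_BETWEEN_ANIMAL_SD = {
    "peak_amplitude_pct": 0.32 * math.sqrt(10),
    "time_to_peak_s": 0.59 * math.sqrt(10),
    "dilation_pct": 1.02 * math.sqrt(5),
}


@dataclass
class VesselSegment:
    """A straight centerline piece with a rest width, in pixel coordinates."""

    p0: tuple[float, float]  # (row, col)
    p1: tuple[float, float]
    width_px: float
    kind: str = "artery"  # "artery" | "vein"
    dilates: bool = False


@dataclass
class GroundTruth:
    """Everything the generator knows that the analysis must recover."""

    vessel_mask: np.ndarray  # bool, vessels at rest
    artery_centerlines: list[VesselSegment]
    amplitude_map: np.ndarray  # injected peak %-change per pixel, >= 0
    dilation_profile: np.ndarray  # per-frame width scale for dilating segments
    response_kernel: np.ndarray  # per-frame weights in [0, 1], max exactly 1
    response_center: tuple[float, float]
    norm_dist_dilating: np.ndarray  # per-pixel normalized distance fields
    norm_dist_static: np.ndarray

    def vessel_mask_at(self, scale: float) -> np.ndarray:
        """Vessel mask with dilating segments drawn at width scale ``scale``."""
        return (self.norm_dist_dilating <= scale) | (self.norm_dist_static <= 1.0)


def response_kernel(params: ScenarioParams) -> np.ndarray:
    """Gamma-variate hemodynamic kernel sampled on the frame grid.

    Zero before stimulation onset, rising to 1 at ``time_to_peak_s`` after
    onset, then decaying over several seconds. The discrete maximum is
    normalized to exactly 1 so the injected peak amplitude is attained.
    """
    t = np.arange(params.n_frames) / params.frame_rate_hz
    tau = t - params.stim_onset_s
    tp = params.time_to_peak_s
    a = params.kernel_shape
    k = np.zeros(params.n_frames)
    pos = tau > 0
    x = tau[pos] / tp
    k[pos] = x**a * np.exp(a * (1.0 - x))
    if k.max() > 0:
        k /= k.max()
    return k


def _grow_tree(
    rng: np.random.Generator,
    shape: tuple[int, int],
    start: tuple[float, float],
    direction: float,
    width: float,
    *,
    kind: str,
    branch_prob: float,
    depth: int = 0,
) -> list[VesselSegment]:
    """Recursively grow one trunk as jittered segments with thinning children."""
    h, w = shape
    segs: list[VesselSegment] = []
    seg_len = 0.16 * min(h, w)
    r, c = start
    ang = direction
    while width >= 1.2 and depth < 10:
        ang += rng.uniform(-0.45, 0.45)
        length = seg_len * rng.uniform(0.7, 1.3)
        r1 = r + length * math.sin(ang)
        c1 = c + length * math.cos(ang)
        segs.append(VesselSegment((r, c), (r1, c1), width, kind=kind))
        if not (-0.2 * h <= r1 <= 1.2 * h and -0.2 * w <= c1 <= 1.2 * w):
            break
        r, c = r1, c1
        depth += 1
        if rng.random() < branch_prob:
            child_ang = rng.uniform(0.35, 0.9)
            segs += _grow_tree(
                rng, shape, (r, c), ang + child_ang, width * 0.72,
                kind=kind, branch_prob=branch_prob, depth=depth,
            )
            ang -= rng.uniform(0.1, 0.5)
            width *= 0.8
        else:
            width *= 0.93
    return segs


def _point_segment_distance(
    rows: np.ndarray, cols: np.ndarray, seg: VesselSegment
) -> np.ndarray:
    r0, c0 = seg.p0
    r1, c1 = seg.p1
    dr, dc = r1 - r0, c1 - c0
    denom = dr * dr + dc * dc
    if denom == 0:
        return np.hypot(rows - r0, cols - c0)
    t = ((rows - r0) * dr + (cols - c0) * dc) / denom
    t = np.clip(t, 0.0, 1.0)
    return np.hypot(rows - (r0 + t * dr), cols - (c0 + t * dc))


def _normalized_distance_field(
    shape: tuple[int, int], segments: list[VesselSegment], max_scale: float = 1.6
) -> np.ndarray:
    """Per-pixel min over segments of distance / rest half-width.

    Only a bounding box around each segment is visited; outside it the
    normalized distance exceeds ``max_scale`` and can never rasterize.
    """
    h, w = shape
    out = np.full(shape, np.inf)
    for seg in segments:
        half = seg.width_px / 2.0
        margin = half * max_scale + 2.0
        r_lo = max(0, int(math.floor(min(seg.p0[0], seg.p1[0]) - margin)))
        r_hi = min(h, int(math.ceil(max(seg.p0[0], seg.p1[0]) + margin)) + 1)
        c_lo = max(0, int(math.floor(min(seg.p0[1], seg.p1[1]) - margin)))
        c_hi = min(w, int(math.ceil(max(seg.p0[1], seg.p1[1]) + margin)) + 1)
        if r_lo >= r_hi or c_lo >= c_hi:
            continue
        rows, cols = np.mgrid[r_lo:r_hi, c_lo:c_hi].astype(float)
        d = _point_segment_distance(rows, cols, seg) / half
        box = out[r_lo:r_hi, c_lo:c_hi]
        np.minimum(box, d, out=box)
    return out


def _split_at_footprint(
    segments: list[VesselSegment], center: tuple[float, float], r_fp: float
) -> list[VesselSegment]:
    """Split segments where they cross the footprint circle.

    After splitting, every piece lies entirely inside or outside the circle
    (up to its half-width overhang), so the dilating set follows the
    footprint boundary rather than segment granularity.
    """
    out: list[VesselSegment] = []
    for seg in segments:
        r0, c0 = seg.p0
        r1, c1 = seg.p1
        dr, dc = r1 - r0, c1 - c0
        fr, fc = r0 - center[0], c0 - center[1]
        a = dr * dr + dc * dc
        b = 2.0 * (fr * dr + fc * dc)
        cc = fr * fr + fc * fc - r_fp * r_fp
        cuts = [0.0, 1.0]
        disc = b * b - 4.0 * a * cc
        if a > 0 and disc > 0:
            sq = math.sqrt(disc)
            for t in ((-b - sq) / (2 * a), (-b + sq) / (2 * a)):
                if 1e-9 < t < 1.0 - 1e-9:
                    cuts.append(t)
        cuts.sort()
        for t0, t1 in zip(cuts[:-1], cuts[1:]):
            if t1 - t0 < 1e-9:
                continue
            p0 = (r0 + t0 * dr, c0 + t0 * dc)
            p1 = (r0 + t1 * dr, c0 + t1 * dc)
            out.append(VesselSegment(p0, p1, seg.width_px, kind=seg.kind))
    return out


def generate_vessel_tree(params: ScenarioParams) -> GroundTruth:
    """Lay out a branching pial vasculature and the injected response.

    Draws >=2 artery trunks with thinning children plus wider non-dilating
    veins, rasterizes them, and builds the amplitude map (Gaussian footprint
    around the response center), the gamma-variate temporal kernel and the
    per-frame width-scale profile for arteries inside the footprint.
    Deterministic for a fixed ``rng_seed``.
    """
    params.validate()
    rng = np.random.default_rng(np.random.SeedSequence([int(params.rng_seed), 11]))
    h, w = params.image_height_px, params.image_width_px
    shape = (h, w)

    center = (
        h / 2.0 + rng.uniform(-0.05, 0.05) * h,
        w / 2.0 + rng.uniform(-0.05, 0.05) * w,
    )

    # trunk arteries are ~0.24 mm wide irrespective of the field of view
    trunk_w = 0.24 / params.pixel_size_mm * params.vessel_width_scale
    trunk_w = max(trunk_w, 2.5 * params.vessel_width_scale)
    segments: list[VesselSegment] = []

    # trunk 0 is the feeding artery: routed from a border point straight
    # through the response center so the footprint always contains artery
    side0 = int(rng.integers(0, 4))
    if side0 == 0:
        start0 = (0.0, rng.uniform(0.2, 0.8) * w)
    elif side0 == 1:
        start0 = (float(h - 1), rng.uniform(0.2, 0.8) * w)
    elif side0 == 2:
        start0 = (rng.uniform(0.2, 0.8) * h, 0.0)
    else:
        start0 = (rng.uniform(0.2, 0.8) * h, float(w - 1))
    ang0 = math.atan2(center[0] - start0[0], center[1] - start0[1])
    mid0 = (
        (start0[0] + center[0]) / 2.0 + rng.uniform(-0.03, 0.03) * h,
        (start0[1] + center[1]) / 2.0 + rng.uniform(-0.03, 0.03) * w,
    )
    w0 = trunk_w * rng.uniform(0.9, 1.1)
    segments.append(VesselSegment(start0, mid0, w0, kind="artery"))
    segments.append(VesselSegment(mid0, center, w0 * 0.95, kind="artery"))
    segments += _grow_tree(
        rng, shape, center, ang0 + rng.uniform(-0.2, 0.2), w0 * 0.9,
        kind="artery", branch_prob=0.5, depth=2,
    )

    n_arteries = int(rng.integers(1, 3))
    sides = rng.permutation(4)
    for i in range(n_arteries):
        side = sides[i % 4]
        if side == 0:  # top
            start, ang = (0.0, rng.uniform(0.15, 0.85) * w), math.pi / 2
        elif side == 1:  # bottom
            start, ang = (float(h - 1), rng.uniform(0.15, 0.85) * w), -math.pi / 2
        elif side == 2:  # left
            start, ang = (rng.uniform(0.15, 0.85) * h, 0.0), 0.0
        else:  # right
            start, ang = (rng.uniform(0.15, 0.85) * h, float(w - 1)), math.pi
        ang += rng.uniform(-0.3, 0.3)
        segments += _grow_tree(
            rng, shape, start, ang, trunk_w * rng.uniform(0.85, 1.15),
            kind="artery", branch_prob=0.45,
        )
    for _ in range(int(rng.integers(1, 3))):  # veins: wider, sparser, static
        side = int(rng.integers(0, 4))
        if side == 0:
            start, ang = (0.0, rng.uniform(0.1, 0.9) * w), math.pi / 2
        elif side == 1:
            start, ang = (float(h - 1), rng.uniform(0.1, 0.9) * w), -math.pi / 2
        elif side == 2:
            start, ang = (rng.uniform(0.1, 0.9) * h, 0.0), 0.0
        else:
            start, ang = (rng.uniform(0.1, 0.9) * h, float(w - 1)), math.pi
        segments += _grow_tree(
            rng, shape, start, ang + rng.uniform(-0.3, 0.3), trunk_w * 1.6,
            kind="vein", branch_prob=0.2,
        )

    # split artery segments at the footprint circle so exactly the pieces
    # inside the responsive footprint dilate
    r_fp = params.footprint_radius_px
    segments = _split_at_footprint(segments, center, r_fp)
    for seg in segments:
        mr = (seg.p0[0] + seg.p1[0]) / 2.0
        mc = (seg.p0[1] + seg.p1[1]) / 2.0
        seg.dilates = (
            seg.kind == "artery"
            and math.hypot(mr - center[0], mc - center[1]) <= r_fp
        )

    dilating = [s for s in segments if s.dilates]
    static = [s for s in segments if not s.dilates]
    nd_dil = _normalized_distance_field(shape, dilating)
    nd_sta = _normalized_distance_field(shape, static)
    vessel_mask = (nd_dil <= 1.0) | (nd_sta <= 1.0)
    if not vessel_mask.any():
        raise ValueError("image too small to fit the minimum vessel tree")

    rows, cols = np.mgrid[0:h, 0:w].astype(float)
    d2 = (rows - center[0]) ** 2 + (cols - center[1]) ** 2
    sigma = r_fp / 2.0
    amplitude_map = params.peak_amplitude_pct * np.exp(-d2 / (2.0 * sigma**2))

    kernel = response_kernel(params)
    dilation_profile = 1.0 + params.dilation_pct / 100.0 * kernel

    return GroundTruth(
        vessel_mask=vessel_mask,
        artery_centerlines=segments,
        amplitude_map=amplitude_map,
        dilation_profile=dilation_profile,
        response_kernel=kernel,
        response_center=center,
        norm_dist_dilating=nd_dil,
        norm_dist_static=nd_sta,
    )


def rasterize_at_scale(truth: GroundTruth, scale: float) -> np.ndarray:
    """Rasterization oracle: the vessel mask with dilating widths scaled."""
    return truth.vessel_mask_at(scale)


def render_trials(params: ScenarioParams, truth: GroundTruth) -> TrialSet:
    """Render the full trial set for one animal.

    The noiseless trace of every pixel is ``baseline * (1 -
    amplitude_map/100 * kernel[t])`` where the baseline is the rest image
    (tissue at ``baseline_counts``, vessels ``vessel_contrast`` darker);
    dilating artery segments are re-rasterized every frame at the
    width-scale given by the dilation profile. Each trial then receives its
    own oscillation phases and white noise from an independent sub-seed.
    """
    params.validate()
    if truth.amplitude_map.shape != (params.image_height_px, params.image_width_px):
        raise ValueError("ground truth does not match params dimensions")
    counts = params.baseline_counts
    kernel = truth.response_kernel
    scales = truth.dilation_profile
    resp = 1.0 - truth.amplitude_map[None, :, :] / 100.0 * kernel[:, None, None]

    if np.all(scales == scales[0]):
        mask = truth.vessel_mask_at(scales[0])[None, :, :]
    else:
        mask = (
            truth.norm_dist_dilating[None, :, :] <= scales[:, None, None]
        ) | (truth.norm_dist_static <= 1.0)[None, :, :]
    rest = counts * (1.0 - params.vessel_contrast * mask)
    if params.blur_sigma_px > 0:
        # optical point-spread blur of the vessel scene; the amplitude map is
        # far smoother than the PSF, so blurring the rest image and applying
        # the multiplicative response afterwards is exact for its purposes
        from scipy import ndimage

        rest = np.stack(
            [ndimage.gaussian_filter(f, params.blur_sigma_px) for f in rest]
        )
    noiseless = rest * resp

    t = np.arange(params.n_frames) / params.frame_rate_hz
    trials = []
    for i in range(params.n_trials):
        rng = np.random.default_rng(
            np.random.SeedSequence([int(params.rng_seed), 23, i])
        )
        osc = np.zeros(params.n_frames)
        for freq, amp in params.osc_components:
            phase = rng.uniform(0.0, 2.0 * math.pi)
            osc += amp / 100.0 * np.sin(2.0 * math.pi * freq * t + phase)
        frames = noiseless * (1.0 + osc[:, None, None])
        if params.noise_sd_pct > 0:
            frames = frames + rng.normal(
                0.0, params.noise_sd_pct / 100.0 * counts, size=frames.shape
            )
        trials.append(
            OISMovie(
                frames=np.maximum(frames, 0.0),
                frame_rate_hz=params.frame_rate_hz,
                pixel_size_mm=params.pixel_size_mm,
                stim_onset_s=params.stim_onset_s,
                stim_duration_s=params.stim_duration_s,
                n_baseline_frames=params.n_baseline_frames,
            )
        )
    return TrialSet(trials)


def render_reference_image(
    params: ScenarioParams, truth: GroundTruth, noise_sd_counts: float | None = None
) -> np.ndarray:
    """A single resting-state frame (no stimulus), e.g. for segmentation.

    Equivalent to one noisy baseline frame of :func:`render_trials`;
    ``noise_sd_counts`` defaults to the scenario's white-noise SD.
    """
    from scipy import ndimage

    rest = params.baseline_counts * (1.0 - params.vessel_contrast * truth.vessel_mask)
    if params.blur_sigma_px > 0:
        rest = ndimage.gaussian_filter(rest, params.blur_sigma_px)
    if noise_sd_counts is None:
        noise_sd_counts = params.noise_sd_pct / 100.0 * params.baseline_counts
    if noise_sd_counts > 0:
        rng = np.random.default_rng(np.random.SeedSequence([int(params.rng_seed), 29]))
        rest = rest + rng.normal(0.0, noise_sd_counts, size=rest.shape)
    return np.maximum(rest, 0.0)


@dataclass
class AnimalSpec:
    animal_id: str
    group: str
    params: ScenarioParams


@dataclass
class Cohort:
    """A two-group cohort of synthetic animals.

    Trials are rendered lazily (one animal's 8-trial stack is ~200 MB at the
    default 128x128 geometry) via :meth:`render_animal`.
    """

    animals: list[AnimalSpec]

    def params_table(self) -> pd.DataFrame:
        """Ground-truth table of each animal's injected parameters."""
        rows = []
        for a in self.animals:
            rows.append(
                {
                    "animal": a.animal_id,
                    "group": a.group,
                    "peak_amplitude_pct": a.params.peak_amplitude_pct,
                    "time_to_peak_s": a.params.time_to_peak_s,
                    "dilation_pct": a.params.dilation_pct,
                    "rng_seed": a.params.rng_seed,
                }
            )
        return pd.DataFrame(rows)

    def render_animal(self, spec: AnimalSpec) -> tuple[GroundTruth, TrialSet]:
        truth = generate_vessel_tree(spec.params)
        return truth, render_trials(spec.params, truth)

    def iter_rendered(self):
        for spec in self.animals:
            truth, trials = self.render_animal(spec)
            yield spec, truth, trials


def _sample_animal(
    base: ScenarioParams, sds: dict, rng: np.random.Generator
) -> ScenarioParams:
    draw = {}
    for key, sd in sds.items():
        val = rng.normal(getattr(base, key), sd)
        if key in ("peak_amplitude_pct", "dilation_pct"):
            val = max(val, 0.0)  # truncate: negative effect sizes are unphysical
        if key == "time_to_peak_s":
            val = float(np.clip(val, 0.5, base.stim_duration_s + 5.0))
        draw[key] = float(val)
    draw["rng_seed"] = int(rng.integers(0, 2**31 - 1))
    return replace(base, **draw)


def generate_cohort(
    control: ScenarioParams = CONTROL_PARAMS,
    stress: ScenarioParams = STRESS_PARAMS,
    n_per_group: int = 10,
    rng_seed: int = 0,
    control_sds: dict | None = None,
    stress_sds: dict | None = None,
) -> Cohort:
    """Sample a two-group cohort around the group-mean scenario parameters.

    Per-animal peak amplitude, time-to-peak and dilation are drawn from
    normal distributions centred on the group defaults with between-animal
    SDs recovered from the printed group SEMs (``SD = SEM * sqrt(n)``).
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    control_sds = CONTROL_BETWEEN_ANIMAL_SD if control_sds is None else control_sds
    stress_sds = STRESS_BETWEEN_ANIMAL_SD if stress_sds is None else stress_sds
    rng = np.random.default_rng(np.random.SeedSequence([int(rng_seed), 37]))
    animals = []
    for i in range(n_per_group):
        animals.append(
            AnimalSpec(f"control_{i:02d}", "control", _sample_animal(control, control_sds, rng))
        )
    for i in range(n_per_group):
        animals.append(
            AnimalSpec(f"stress_{i:02d}", "stress", _sample_animal(stress, stress_sds, rng))
        )
    return Cohort(animals)


def save_scenario(params: ScenarioParams, truth: GroundTruth, trials: TrialSet, outdir) -> None:
    """Write trials as 16-bit multi-page TIFFs plus ground-truth sidecars."""
    from . import io as _io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for i, movie in enumerate(trials):
        _io.write_trial_stack(movie, outdir / f"trial_{i:02d}.tif")
    _io.write_mask(truth.vessel_mask, outdir / "vessel_mask.tif")
    sheet = {
        "peak_amplitude_pct": params.peak_amplitude_pct,
        "time_to_peak_s": params.time_to_peak_s,
        "dilation_pct": params.dilation_pct,
        "footprint_radius_mm": params.footprint_radius_mm,
        "noise_sd_pct": params.noise_sd_pct,
        "rng_seed": params.rng_seed,
        "response_center_row": truth.response_center[0],
        "response_center_col": truth.response_center[1],
    }
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(sheet, fh, indent=2)
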