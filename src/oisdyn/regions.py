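"""SD-map computation and decomposition into the four characteristic regions.

The SD map is the per-pixel temporal standard deviation of the (averaged,
filtered) intensity stack, using the population divisor N. After 3x3
Gaussian smoothing, pixels whose SD exceeds the map mean + 2 SD form the
"responsive area"; intersecting it with the thresholded vessel probability
map yields the responsive pial artery, the responsive tissue, and the
non-responsive vessels.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .io import OISMovie
from .segmentation import VesselProbabilityMap

__all__ = [
    "SDMap",
    "RegionMasks",
    "compute_sd_map",
    "gaussian_kernel_3x3",
    "smooth_map",
    "responsive_mask",
    "decompose_regions",
]


@dataclass
class SDMap:
    """Per-pixel temporal standard deviation (population form, divisor N)."""

    sd: np.ndarray
    n_frames_used: int
    smoothed: bool = False


@dataclass
class RegionMasks:
    """The four characteristic regions, all sharing one geometry.

    ``responsive_pial_artery`` and ``responsive_tissue`` partition the
    responsive area; ``nonresponsive_vessels`` is the vessel mask outside it.
    """

    responsive_area: np.ndarray
    responsive_pial_artery: np.ndarray
    nonresponsive_vessels: np.ndarray
    responsive_tissue: np.ndarray

    def as_dict(self) -> dict[str, np.ndarray]:
        return {
            "responsive_area": self.responsive_area,
            "responsive_pial_artery": self.responsive_pial_artery,
            "nonresponsive_vessels": self.nonresponsive_vessels,
            "responsive_tissue": self.responsive_tissue,
        }


def compute_sd_map(movie: OISMovie) -> SDMap:
    """SD over frames of each pixel, divisor N (not N-1)."""
    n = movie.n_frames
    if n < 2:
        raise ValueError("need at least 2 frames")
    sd = np.std(movie.frames.astype(np.float64), axis=0, ddof=0)
    return SDMap(sd=sd, n_frames_used=n)


def gaussian_kernel_3x3(sigma: float = 0.8) -> np.ndarray:
    """Normalized 3x3 Gaussian kernel (weights sum to 1)."""
    ax = np.array([-1.0, 0.0, 1.0])
    g = np.exp(-(ax**2) / (2.0 * sigma**2))
    k = np.outer(g, g)
    return k / k.sum()


def smooth_map(sd_or_map, sigma: float = 0.8):
    """Convolve a 2-D map with the normalized 3x3 Gaussian, reflect-padded.

    Accepts either a raw 2-D array (returns an array) or an :class:`SDMap`
    (returns an :class:`SDMap` flagged as smoothed).
    """
    kernel = gaussian_kernel_3x3(sigma)
    if isinstance(sd_or_map, SDMap):
        smoothed = ndimage.convolve(sd_or_map.sd, kernel, mode="reflect")
        return replace(sd_or_map, sd=smoothed, smoothed=True)
    arr = np.asarray(sd_or_map, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D map")
    return ndimage.convolve(arr, kernel, mode="reflect")


def responsive_mask(sdmap: SDMap) -> np.ndarray:
    """Pixels whose SD strictly exceeds the map mean + 2 SD (population).

    Low-variation pixels carry no response and are excluded; the threshold
    is computed over all pixels of the smoothed SD map.
    """
    if not sdmap.smoothed:
        raise ValueError("responsive_mask expects a smoothed SD map; call smooth_map first")
    sd = sdmap.sd
    thr = sd.mean() + 2.0 * sd.std(ddof=0)
    return sd > thr


def decompose_regions(
    responsive: np.ndarray,
    prob_map: VesselProbabilityMap,
    vessel_threshold: float = 0.6,
) -> RegionMasks:
    """Intersect the responsive mask with the thresholded vessel map.

    (Thresholding the probability map and intersecting is boolean-equivalent
    to multiplying the probability map into the mask and thresholding.)
    """
    responsive = np.asarray(responsive, dtype=bool)
    if responsive.shape != prob_map.prob.shape:
        raise ValueError("responsive mask and probability map geometries differ")
    vessel = prob_map.prob > vessel_threshold
    return RegionMasks(
        responsive_area=responsive,
        responsive_pial_artery=responsive & vessel,
        nonresponsive_vessels=vessel & ~responsive,
        responsive_tissue=responsive & ~vessel,
    )
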