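"""Image-stack and table I/O for optical intrinsic signal (OIS) recordings.

A trial is a multi-page grayscale TIFF (one page per frame). Acquisition
metadata (frame rate, pixel size, stimulation timing) travels in a YAML
sidecar next to the stack, because TIFF tags are dialect-prone. Masks are
single-page 0/255 images; metric tables are CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "OISMovie",
    "TrialSet",
    "LoadError",
    "read_trial_stack",
    "write_trial_stack",
    "read_mask",
    "write_mask",
    "write_results_table",
    "read_results_table",
]

#: metadata keys serialized to the YAML sidecar, in stable order
_META_KEYS = (
    "frame_rate_hz",
    "pixel_size_mm",
    "stim_onset_s",
    "stim_duration_s",
    "n_baseline_frames",
)


class LoadError(RuntimeError):
    """A stack or sidecar could not be read or is internally inconsistent."""


@dataclass
class OISMovie:
    """A single trial: frame stack plus acquisition metadata.

    frames are indexed ``(frame, row, col)``, row 0 at the image top, in
    arbitrary non-negative intensity units (camera counts).
    """

    frames: np.ndarray
    frame_rate_hz: float
    pixel_size_mm: float
    stim_onset_s: float
    stim_duration_s: float
    n_baseline_frames: int = 50

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (frame, row, col) 3-D array")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frames contain non-finite values")
        if np.any(self.frames < 0):
            raise ValueError("frames contain negative intensities")
        if self.n_baseline_frames >= self.frames.shape[0]:
            raise ValueError("n_baseline_frames must be < number of frames")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate_hz

    @property
    def stim_onset_frame(self) -> int:
        return int(round(self.stim_onset_s * self.frame_rate_hz))

    @property
    def times_s(self) -> np.ndarray:
        """Acquisition time of each frame, seconds from recording start."""
        return np.arange(self.n_frames) / self.frame_rate_hz

    def metadata(self) -> dict:
        return {
            "frame_rate_hz": float(self.frame_rate_hz),
            "pixel_size_mm": float(self.pixel_size_mm),
            "stim_onset_s": float(self.stim_onset_s),
            "stim_duration_s": float(self.stim_duration_s),
            "n_baseline_frames": int(self.n_baseline_frames),
        }

    def with_frames(self, frames: np.ndarray) -> "OISMovie":
        """Copy of this movie with the frame data replaced."""
        return replace(self, frames=frames)


@dataclass
class TrialSet:
    """An ordered list of repeated trials with identical shape and metadata."""

    trials: list[OISMovie] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.trials:
            raise ValueError("TrialSet needs at least one trial")
        ref = self.trials[0]
        for t in self.trials[1:]:
            if t.shape != ref.shape:
                raise ValueError("all trials must share the same shape")
            if t.metadata() != ref.metadata():
                raise ValueError("all trials must share the same metadata")

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    def __getitem__(self, i):
        return self.trials[i]


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".yaml")


def write_trial_stack(movie: OISMovie, path, *, as_uint16: bool = True) -> Path:
    """Write a trial as a multi-page TIFF plus a YAML metadata sidecar.

    With ``as_uint16`` (the default) intensities are rounded into the 16-bit
    range; pass ``False`` to keep 32-bit float pages.
    """
    path = Path(path)
    frames = movie.frames
    if as_uint16:
        frames = np.clip(np.rint(frames), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    else:
        frames = frames.astype(np.float32)
    tifffile.imwrite(path, frames, photometric="minisblack")
    meta = movie.metadata()
    with open(_sidecar_path(path), "w") as fh:
        yaml.safe_dump({k: meta[k] for k in _META_KEYS}, fh, sort_keys=False)
    return path


def read_trial_stack(path, *, metadata: dict | None = None) -> OISMovie:
    """Read a multi-page TIFF trial stack.

    Metadata comes from the YAML sidecar written by :func:`write_trial_stack`,
    or from the ``metadata`` mapping (which takes precedence key-by-key).
    """
    path = Path(path)
    if not path.exists():
        raise LoadError(f"no such stack: {path}")
    try:
        with tifffile.TiffFile(path) as tif:
            shapes = {p.shape for p in tif.pages}
            if len(shapes) != 1:
                raise LoadError(f"inconsistent page shapes in {path}: {sorted(shapes)}")
            frames = tif.asarray()
    except LoadError:
        raise
    except Exception as exc:  # pragma: no cover - tifffile's own failures
        raise LoadError(f"could not read {path}: {exc}") from exc
    if frames.ndim == 2:
        frames = frames[None]
    meta: dict = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        with open(sidecar) as fh:
            meta.update(yaml.safe_load(fh) or {})
    if metadata:
        meta.update(metadata)
    missing = [k for k in _META_KEYS if k not in meta and k != "n_baseline_frames"]
    if missing:
        raise LoadError(f"missing metadata for {path}: {missing}")
    return OISMovie(frames=frames.astype(np.float64), **{k: meta[k] for k in _META_KEYS if k in meta})


def write_mask(mask: np.ndarray, path) -> Path:
    """Write a boolean mask as a 0/255 single-page image (TIFF or PNG)."""
    path = Path(path)
    img = np.where(np.asarray(mask, dtype=bool), 255, 0).astype(np.uint8)
    if path.suffix.lower() == ".png":
        import imageio.v3 as iio

        iio.imwrite(path, img)
    else:
        tifffile.imwrite(path, img, photometric="minisblack")
    return path


def read_mask(path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() == ".png":
        import imageio.v3 as iio

        img = iio.imread(path)
    else:
        img = tifffile.imread(path)
    return np.asarray(img) > 127


def write_results_table(records, path) -> Path:
    """Write metric records (mappings with animal/group/metric fields) as CSV.

    Column order is stable: first the conventional identifier columns that are
    present, then any remaining keys in first-seen order. An empty record list
    yields a header-only CSV.
    """
    records = list(records)
    preferred = ["animal", "group", "region", "metric", "value"]
    seen: list[str] = []
    for rec in records:
        for k in rec:
            if k not in seen:
                seen.append(k)
    cols = [c for c in preferred if c in seen] + [c for c in seen if c not in preferred]
    if not records:
        cols = preferred
    df = pd.DataFrame.from_records(records, columns=cols)
    df.to_csv(path, index=False, float_format="%.12g")
    return Path(path)


def read_results_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
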