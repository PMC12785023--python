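"""Spectral preprocessing: TIC normalization, mass windowing, binning.

The preprocessing chain mirrors routine MSI practice: each pixel spectrum is
rescaled so its total ion current (TIC) matches a common target, the axis is
split into mass-range windows for windowed analysis, and peak lists from
processed-mode files are resampled onto a fixed-width bin grid.

Order matters: TIC normalization is applied on the full recorded range
first, and windowing afterwards, so the per-window spectra keep the
relative weights they had in the full spectrum.  Normalization and
windowing only commute when the window covers the whole axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datacube import MSIDataCube

__all__ = [
    "MassWindow",
    "CANONICAL_WINDOWS",
    "PreprocessConfig",
    "tic_normalize",
    "window_mass_range",
    "bin_spectra",
]


@dataclass(frozen=True)
class MassWindow:
    """A half-open mass range [low, high) in Da.

    The terminal window of a partition closes at its upper edge
    (``inclusive_high=True``) so the full acquisition range is covered.
    """

    low: float
    high: float
    inclusive_high: bool = False

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError(f"window requires low < high, got [{self.low}, {self.high})")

    @property
    def label(self) -> str:
        return f"{self.low:g}-{self.high:g}"

    def contains(self, mz: np.ndarray) -> np.ndarray:
        mz = np.asarray(mz, dtype=np.float64)
        if self.inclusive_high:
            return (mz >= self.low) & (mz <= self.high)
        return (mz >= self.low) & (mz < self.high)


#: The four canonical acquisition-range sections, 200-1000 Da.
CANONICAL_WINDOWS = (
    MassWindow(200.0, 400.0),
    MassWindow(400.0, 600.0),
    MassWindow(600.0, 800.0),
    MassWindow(800.0, 1000.0, inclusive_high=True),
)

FULL_RANGE = MassWindow(200.0, 1000.0, inclusive_high=True)


@dataclass(frozen=True)
class PreprocessConfig:
    """Preprocessing parameters.

    bin_width : Da, fixed-width resampling grid (default 0.1, the same
        scale as the annotation mass tolerance).
    tic_target : ``"grand_mean"`` or an explicit positive float.
    zero_tic_policy : ``"keep_zero_and_flag"`` or ``"drop_pixel"``.
    """

    bin_width: float = 0.1
    tic_target: str | float = "grand_mean"
    zero_tic_policy: str = "keep_zero_and_flag"

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if isinstance(self.tic_target, str) and self.tic_target != "grand_mean":
            raise ValueError("tic_target must be 'grand_mean' or a positive number")
        if not isinstance(self.tic_target, str) and self.tic_target <= 0:
            raise ValueError("explicit tic_target must be positive")
        if self.zero_tic_policy not in ("keep_zero_and_flag", "drop_pixel"):
            raise ValueError(f"unknown zero_tic_policy {self.zero_tic_policy!r}")


DEFAULT_CONFIG = PreprocessConfig()


def tic_normalize(cube: MSIDataCube, config: PreprocessConfig = DEFAULT_CONFIG) -> MSIDataCube:
    """Rescale every pixel spectrum to a common total ion current.

    The target is the grand mean of raw per-pixel TICs (so the intensity
    scale stays interpretable), or an explicit value from *config*.
    Zero-TIC pixels cannot be rescaled; they are kept as zeros and flagged
    in provenance, or dropped, per ``config.zero_tic_policy``.
    """
    tic = cube.pixel_tic()
    positive = tic > 0
    if not positive.any():
        raise ValueError("all pixels have zero TIC; nothing to normalize")
    if isinstance(config.tic_target, str):
        target = float(tic.mean())
    else:
        target = float(config.tic_target)

    scale = np.ones_like(tic)
    scale[positive] = target / tic[positive]
    inten = cube.intensities.astype(np.float64) * scale[:, None]

    zero_idx = np.flatnonzero(~positive)
    if zero_idx.size and config.zero_tic_policy == "drop_pixel":
        keep = positive
        cube_out = cube.replace(pixel_coords=cube.pixel_coords[keep],
                                intensities=inten[keep])
        note = f"dropped {zero_idx.size} zero-TIC pixels"
    else:
        cube_out = cube.replace(intensities=inten)
        note = (f"kept {zero_idx.size} zero-TIC pixels at indices {zero_idx.tolist()}"
                if zero_idx.size else "no zero-TIC pixels")
    cube_out.provenance.append(
        f"tic_normalize(target={target:.6g}, policy={config.zero_tic_policy}); {note}"
    )
    return cube_out


def window_mass_range(cube: MSIDataCube, window: MassWindow) -> MSIDataCube:
    """Restrict the cube to bins whose centers fall inside *window*."""
    mask = window.contains(cube.mz_axis)
    if not mask.any():
        raise ValueError(f"no m/z bins fall inside window {window.label} Da")
    out = cube.replace(mz_axis=cube.mz_axis[mask], intensities=cube.intensities[:, mask])
    out.provenance.append(f"window_mass_range({window.label} Da, {int(mask.sum())} bins)")
    return out


def bin_spectra(peaklists, pixel_coords, width: int, height: int,
                bin_width: float = 0.1,
                mass_range: MassWindow = FULL_RANGE,
                mode: str = "negative") -> MSIDataCube:
    """Resample per-pixel (m/z, intensity) peak lists onto a fixed bin grid.

    Bins are anchored at ``mass_range.low`` with centers
    ``low + (i + 0.5) * bin_width`` and half-open ``[edge, edge+width)``
    assignment; intensities falling in the same bin are summed.  Bins empty
    across all pixels are dropped.  Peaks outside the range are silently
    excluded but counted in provenance.

    Parameters
    ----------
    peaklists : sequence of (mz_array, intensity_array) pairs, one per pixel.
    pixel_coords : (n_pixels, 2) integer (x, y) positions.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    pixel_coords = np.asarray(pixel_coords, dtype=np.intp)
    n = len(peaklists)
    if n != pixel_coords.shape[0]:
        raise ValueError("peaklists and pixel_coords length mismatch")

    n_bins = int(np.ceil((mass_range.high - mass_range.low) / bin_width))
    full = np.zeros((n, n_bins), dtype=np.float64)
    excluded = 0
    for p, (mzs, ints) in enumerate(peaklists):
        mzs = np.asarray(mzs, dtype=np.float64)
        ints = np.asarray(ints, dtype=np.float64)
        if mzs.size == 0:
            continue
        keep = mass_range.contains(mzs)
        excluded += int((~keep).sum())
        idx = np.floor((mzs[keep] - mass_range.low) / bin_width).astype(np.intp)
        # the closed upper edge of a terminal window folds into the last bin
        idx = np.minimum(idx, n_bins - 1)
        np.add.at(full[p], idx, ints[keep])

    nonempty = full.any(axis=0)
    if not nonempty.any():
        raise ValueError("no peaks fall inside the requested mass range")
    centers = mass_range.low + (np.arange(n_bins) + 0.5) * bin_width
    cube = MSIDataCube(
        width=width, height=height, pixel_coords=pixel_coords,
        mz_axis=centers[nonempty], intensities=full[:, nonempty].astype(np.float32),
        mode=mode,
        provenance=[
            f"bin_spectra(width={bin_width} Da, range={mass_range.label}, "
            f"{int(nonempty.sum())} nonempty bins, {excluded} out-of-range peaks excluded)"
        ],
    )
    return cube
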