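"""Core MSI datacube model, imzML I/O and deterministic label-map rendering.

An imaging-mass-spectrometry (MSI) acquisition is a raster of pixels, each
carrying a full mass spectrum.  This module holds the in-memory container
(:class:`MSIDataCube`), reads and writes the open imzML 1.1 interchange
format (continuous and processed mode) via :mod:`pyimzml`, and renders
cluster label maps to PNG with a bit-exact, pinned encoder configuration.

The PNG pinning matters scientifically: downstream analysis uses the byte
size of the losslessly compressed segmentation image as a surrogate for its
information content, so any encoder nondeterminism would corrupt that
statistic.  Rendering is therefore a pure function of (labels, palette):
8-bit truecolor RGB, maximum-effort deflate, no interlace, no ancillary
chunks.  The encoder identity is recorded in cube provenance.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import PIL
from PIL import Image

__all__ = [
    "NO_TISSUE",
    "MSIDataCube",
    "LabelMap",
    "Palette",
    "FormatError",
    "read_imzml",
    "write_imzml",
    "render_png",
    "save_cube",
    "load_cube",
]

#: Sentinel label for grid positions that carry no tissue (absent pixels).
NO_TISSUE = -1

ENCODER_ID = f"Pillow {PIL.__version__} PNG (RGB, compress_level=9, no ancillary chunks)"


class FormatError(ValueError):
    """Raised when an input file violates the expected format."""


@dataclass
class MSIDataCube:
    """A pixel raster with a shared m/z axis and per-pixel intensity rows.

    Parameters
    ----------
    width, height : int
        Grid extent in pixels; coordinates are 0-based, x rightward,
        y downward (imzML top-left origin convention).
    pixel_coords : ndarray of shape (n_pixels, 2)
        Integer (x, y) grid positions; unique, within bounds.  The grid may
        be non-rectangular (tissue does not fill the bounding box).
    mz_axis : ndarray of shape (n_bins,)
        Strictly increasing bin-center m/z values in Da.
    intensities : ndarray of shape (n_pixels, n_bins)
        Nonnegative intensities, stored as float32 (sufficient for TOF
        dynamic range at half the memory).
    mode : str
        Ionization mode, ``"positive"`` or ``"negative"``.
    raster_um : float
        Pixel pitch in micrometres (default 30).
    provenance : list of str
        Append-only processing log; every transforming operation appends.
    """

    width: int
    height: int
    pixel_coords: np.ndarray
    mz_axis: np.ndarray
    intensities: np.ndarray
    mode: str = "negative"
    raster_um: float = 30.0
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.pixel_coords = np.asarray(self.pixel_coords, dtype=np.intp)
        self.mz_axis = np.asarray(self.mz_axis, dtype=np.float64)
        # float32 is the at-rest dtype (I/O, phantoms); float64 survives so
        # that exact arithmetic contracts (e.g. TIC targets) hold downstream
        self.intensities = np.asarray(self.intensities)
        if self.intensities.dtype != np.float64:
            self.intensities = self.intensities.astype(np.float32)
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        if self.pixel_coords.ndim != 2 or self.pixel_coords.shape[1] != 2:
            raise ValueError("pixel_coords must have shape (n_pixels, 2)")
        n = self.pixel_coords.shape[0]
        if n == 0:
            raise ValueError("cube has no pixels")
        if self.intensities.shape != (n, self.mz_axis.shape[0]):
            raise ValueError(
                f"intensities shape {self.intensities.shape} inconsistent with "
                f"{n} pixels x {self.mz_axis.shape[0]} bins"
            )
        if self.mz_axis.size and np.any(np.diff(self.mz_axis) <= 0):
            raise ValueError("mz_axis must be strictly increasing")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be nonnegative")
        x, y = self.pixel_coords[:, 0], self.pixel_coords[:, 1]
        if x.min() < 0 or y.min() < 0 or x.max() >= self.width or y.max() >= self.height:
            raise ValueError("pixel coordinates outside the grid")
        flat = y * self.width + x
        if np.unique(flat).size != n:
            raise ValueError("pixel coordinates must be unique")
        if self.mode not in ("positive", "negative"):
            raise ValueError(f"unknown ionization mode {self.mode!r}")

    # -- conveniences -----------------------------------------------------
    @property
    def n_pixels(self) -> int:
        return int(self.pixel_coords.shape[0])

    @property
    def n_bins(self) -> int:
        return int(self.mz_axis.shape[0])

    def pixel_tic(self) -> np.ndarray:
        """Per-pixel total ion current (intensity sum), float64."""
        return self.intensities.astype(np.float64).sum(axis=1)

    def row_major_rank(self) -> np.ndarray:
        """Rank of each pixel in row-major (y, then x) grid order."""
        return self.pixel_coords[:, 1] * self.width + self.pixel_coords[:, 0]

    def replace(self, **kw) -> "MSIDataCube":
        """Copy with selected fields replaced; provenance list is copied."""
        d = dict(
            width=self.width,
            height=self.height,
            pixel_coords=self.pixel_coords,
            mz_axis=self.mz_axis,
            intensities=self.intensities,
            mode=self.mode,
            raster_um=self.raster_um,
            provenance=list(self.provenance),
        )
        d.update(kw)
        return MSIDataCube(**d)


@dataclass
class LabelMap:
    """Per-pixel integer cluster labels on the cube grid.

    ``labels`` is a (height, width) array with values in [0, k) on tissue
    positions and :data:`NO_TISSUE` elsewhere.
    """

    width: int
    height: int
    labels: np.ndarray
    k: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int32)
        if self.labels.shape != (self.height, self.width):
            raise ValueError("labels must have shape (height, width)")
        tissue = self.labels[self.labels != NO_TISSUE]
        if tissue.size == 0:
            raise ValueError("label map has no tissue pixels")
        if tissue.min() < 0 or tissue.max() >= self.k:
            raise ValueError("labels out of range [0, k)")
        present = np.unique(tissue)
        if present.size != self.k:
            raise ValueError("every label in [0, k) must occur at least once")

    def tissue_mask(self) -> np.ndarray:
        return self.labels != NO_TISSUE


# Ten maximally distinct 8-bit RGB colors (fixed order) plus background.
_DEFAULT_COLORS = (
    (230, 25, 75),    # red
    (60, 180, 75),    # green
    (0, 130, 200),    # blue
    (255, 225, 25),   # yellow
    (145, 30, 180),   # purple
    (245, 130, 48),   # orange
    (70, 240, 240),   # cyan
    (240, 50, 230),   # magenta
    (128, 128, 128),  # gray
    (170, 110, 40),   # brown
)


@dataclass(frozen=True)
class Palette:
    """Ordered cluster colors plus one background color for NO_TISSUE."""

    colors: tuple = _DEFAULT_COLORS
    background: tuple = (0, 0, 0)

    def __post_init__(self) -> None:
        all_colors = tuple(self.colors) + (tuple(self.background),)
        if len(set(map(tuple, all_colors))) != len(all_colors):
            raise ValueError("palette colors (incl. background) must be pairwise distinct")

    def __len__(self) -> int:
        return len(self.colors)


DEFAULT_PALETTE = Palette()


def render_png(label_map: LabelMap, palette: Palette = DEFAULT_PALETTE,
               path: str | Path | None = None) -> int:
    """Render a label map to PNG with pinned encoder settings.

    One image pixel per raster position, 8-bit RGB, no interlace, no
    ancillary chunks, maximum-effort deflate.  Identical (labels, palette)
    inputs yield byte-identical files.  Returns the byte count; if *path*
    is None the image is encoded in memory only.
    """
    if label_map.k > len(palette):
        raise ValueError(
            f"label map has k={label_map.k} clusters but palette holds only "
            f"{len(palette)} colors; extend the palette"
        )
    lut = np.array(list(palette.colors) + [palette.background], dtype=np.uint8)
    idx = np.where(label_map.labels == NO_TISSUE, len(palette.colors), label_map.labels)
    rgb = lut[idx]
    img = Image.fromarray(rgb, mode="RGB")
    buf = io.BytesIO()
    img.save(buf, format="PNG", compress_level=9)
    data = buf.getvalue()
    if path is not None:
        Path(path).write_bytes(data)
    return len(data)


# ---------------------------------------------------------------------------
# imzML I/O
# ---------------------------------------------------------------------------

def read_imzml(path: str | Path, mode: str | None = None,
               bin_width: float = 0.1) -> MSIDataCube:
    """Read an imzML/ibd pair into an :class:`MSIDataCube`.

    Continuous-mode files adopt the shared m/z axis as-is.  Processed-mode
    files (per-pixel peak lists) are resampled onto a common axis by
    fixed-width binning (delegating to :func:`msimargin.preprocess.bin_spectra`
    with *bin_width*).  Ionization mode is read from the file metadata when
    present, else taken from *mode*.
    """
    from pyimzml.ImzMLParser import ImzMLParser

    path = Path(path)
    ibd = path.with_suffix(".ibd")
    if not ibd.exists():
        raise IOError(f"missing .ibd companion for {path}")
    parser = ImzMLParser(str(path))
    n = len(parser.coordinates)
    if n == 0:
        raise FormatError(f"{path} contains zero spectra")

    file_mode = mode
    continuous = None
    try:
        params = parser.metadata.file_description.param_by_name
        continuous = bool(params.get("continuous", False)) or None
        if params.get("processed"):
            continuous = False
        groups = parser.metadata.referenceable_param_groups
        for g in groups.values():
            gp = g.param_by_name
            if gp.get("negative scan"):
                file_mode = file_mode or "negative"
            if gp.get("positive scan"):
                file_mode = file_mode or "positive"
    except AttributeError:  # metadata layout differs between writers
        pass
    if file_mode is None:
        file_mode = "negative"

    # imzML coordinates are 1-based (x, y[, z]); convert to 0-based.
    coords = np.array([(c[0] - 1, c[1] - 1) for c in parser.coordinates], dtype=np.intp)
    width = int(coords[:, 0].max()) + 1
    height = int(coords[:, 1].max()) + 1

    spectra = []
    for i in range(n):
        mzs, ints = parser.getspectrum(i)
        mzs = np.asarray(mzs, dtype=np.float64)
        if mzs.size > 1 and np.any(np.diff(mzs) < 0):
            raise FormatError(
                f"non-monotone m/z array in spectrum {i} at pixel "
                f"{tuple(coords[i])}"
            )
        spectra.append((mzs, np.asarray(ints, dtype=np.float64)))

    if continuous is None:
        first = spectra[0][0]
        continuous = all(s[0].shape == first.shape and np.array_equal(s[0], first)
                         for s in spectra)

    if continuous:
        mz_axis = spectra[0][0]
        inten = np.vstack([s[1] for s in spectra]).astype(np.float32)
        cube = MSIDataCube(
            width=width, height=height, pixel_coords=coords, mz_axis=mz_axis,
            intensities=np.clip(inten, 0, None), mode=file_mode,
            provenance=[f"read_imzml(continuous) from {path.name}"],
        )
    else:
        from .preprocess import MassWindow, bin_spectra

        lo = min(float(s[0].min()) for s in spectra if s[0].size)
        hi = max(float(s[0].max()) for s in spectra if s[0].size)
        window = MassWindow(np.floor(lo), np.ceil(hi) + bin_width, inclusive_high=True)
        cube = bin_spectra(spectra, coords, width, height, bin_width=bin_width,
                           mass_range=window, mode=file_mode)
        cube.provenance.insert(0, f"read_imzml(processed) from {path.name}")
    return cube


def write_imzml(cube: MSIDataCube, path: str | Path) -> Path:
    """Write a cube as a continuous-mode imzML/ibd pair (float32 payload)."""
    from pyimzml.ImzMLWriter import ImzMLWriter

    path = Path(path)
    polarity = cube.mode
    with ImzMLWriter(str(path), mode="continuous", polarity=polarity,
                     mz_dtype=np.float64, intensity_dtype=np.float32) as writer:
        for i in range(cube.n_pixels):
            x, y = cube.pixel_coords[i]
            writer.addSpectrum(cube.mz_axis, cube.intensities[i].astype(np.float64),
                               (int(x) + 1, int(y) + 1, 1))
    return path


# ---------------------------------------------------------------------------
# Single-file binary cache (header + axis + matrix), for intermediates only.
# ---------------------------------------------------------------------------

def save_cube(cube: MSIDataCube, path: str | Path) -> Path:
    path = Path(path)
    np.savez(
        path,
        width=cube.width, height=cube.height, pixel_coords=cube.pixel_coords,
        mz_axis=cube.mz_axis, intensities=cube.intensities,
        mode=cube.mode, raster_um=cube.raster_um,
        provenance=np.array(cube.provenance, dtype=object),
    )
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def load_cube(path: str | Path) -> MSIDataCube:
    with np.load(path, allow_pickle=True) as z:
        return MSIDataCube(
            width=int(z["width"]), height=int(z["height"]),
            pixel_coords=z["pixel_coords"], mz_axis=z["mz_axis"],
            intensities=z["intensities"], mode=str(z["mode"]),
            raster_um=float(z["raster_um"]),
            provenance=list(z["provenance"]),
        )
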