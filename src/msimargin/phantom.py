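"""Ground-truthed synthetic MSI phantoms.

The phantom emulates the spatial and spectral structure of a resected
colorectal sample imaged at low mass range: a peritumor background, a
tumor with heterogeneous subregions, a thin chemically distinct margin
band, and optionally fat.  Each region carries a peak panel in 200-1000
Da; per-pixel amplitude scatter, a multiplicative TIC drift, and additive
noise emulate acquisition variability.  Two ionization-mode variants
differ in their noise level (the positive mode is noisier, dominating the
low-mass windows).

Discriminant peaks are anchored at the masses reported as margin/tumor
markers in the colorectal MSI literature (465.94, 864.15, 885.75 Da) so
phantom outputs and documentation speak the field's language; their
amplitudes are free generator parameters, not claims about real tissue.

Tumor-versus-peritumor spectral contrast is controlled per mass window
(``contrast_by_window``): differential peaks — the fixed anchors and the
per-case random discriminants — are scaled by the window's multiplier, so
a collection with contrast confined to 800-1000 Da reproduces the study
condition in which only the lipid-range windows delineate the margin.

Everything is deterministic under the seed; a master seed fans out to
per-case and per-mode substreams via ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .datacube import MSIDataCube, write_imzml
from .margin import ROI, ROISet
from .preprocess import CANONICAL_WINDOWS, FULL_RANGE, MassWindow

__all__ = [
    "RegionSpec",
    "PhantomSpec",
    "PhantomTruth",
    "PhantomCase",
    "phantom_spec",
    "make_phantom",
    "make_case_collection",
    "iter_case_collection",
    "write_fixture_suite",
    "DEFAULT_CONTRAST",
]

PEAK_SIGMA_DA = 0.05  # Gaussian peak width on the m/z axis

#: Default per-window tumor/peritumor contrast multipliers for a case
#: collection: discriminant chemistry confined to the lipid-range windows,
#: the condition under which margins are delineable.
DEFAULT_CONTRAST = {"200-400": 0.0, "400-600": 0.0, "600-800": 0.3, "800-1000": 1.0}

#: Full contrast in every window (single-phantom default).
FULL_CONTRAST = {w.label: 1.0 for w in CANONICAL_WINDOWS}


@dataclass
class RegionSpec:
    """One tissue region: a geometry plus its peak panel.

    ``geometry`` kinds: ``full`` (whole grid), ``ellipse`` (cx, cy, rx,
    ry), ``disk`` (cx, cy, r).  Later regions overwrite earlier ones.
    ``peaks`` are (m/z Da, mean amplitude, amplitude CV) triples.
    """

    name: str
    geometry: dict
    peaks: list
    baseline: float = 0.0

    def mask(self, width: int, height: int) -> np.ndarray:
        y, x = np.mgrid[0:height, 0:width]
        g = self.geometry
        kind = g["kind"]
        if kind == "full":
            return np.ones((height, width), dtype=bool)
        if kind == "ellipse":
            return ((x - g["cx"]) / g["rx"]) ** 2 + ((y - g["cy"]) / g["ry"]) ** 2 <= 1.0
        if kind == "disk":
            return (x - g["cx"]) ** 2 + (y - g["cy"]) ** 2 <= g["r"] ** 2
        raise ValueError(f"unknown geometry kind {kind!r}")


@dataclass
class PhantomSpec:
    width: int
    height: int
    regions: list  # of RegionSpec; paint order = list order
    noise_sd: float = 1.0
    tic_drift_cv: float = 0.15
    mode: str = "negative"
    seed: int = 0
    bin_width: float = 0.1
    mass_range: MassWindow = FULL_RANGE


@dataclass
class PhantomTruth:
    """Ground truth for one phantom: region labels, spec, canonical ROIs."""

    region_labels: np.ndarray  # (height, width) index into region_names
    region_names: list
    spec: PhantomSpec
    rois: ROISet

    def binary_truth(self):
        """Tumor-vs-rest labels and a validity mask for segmentation scoring.

        The margin band is a transition zone without a binary ground
        truth; its pixels are excluded from the comparison (standard
        practice for boundary pixels in segmentation evaluation).
        """
        names = self.region_names
        tumor_ids = [i for i, n in enumerate(names) if n.startswith("tumor_core")]
        margin_ids = [i for i, n in enumerate(names) if n == "margin_band"]
        labels = np.isin(self.region_labels, tumor_ids).astype(np.int32)
        valid = ~np.isin(self.region_labels, margin_ids)
        return labels, valid


# ---------------------------------------------------------------------------
# panels and presets
# ---------------------------------------------------------------------------

def _window_of(mz: float) -> str:
    for w in CANONICAL_WINDOWS:
        if w.contains(np.array([mz]))[0]:
            return w.label
    return "none"


def _scale_by_window(peaks, contrast) -> list:
    out = []
    for mz, amp, cv in peaks:
        c = contrast.get(_window_of(mz), 0.0)
        if c > 0:
            out.append((mz, amp * c, cv))
    return out


_COMMON_FIXED = [(437.27, 35.0, 0.1), (810.60, 30.0, 0.1)]
_TUMOR_FIXED = [(212.10, 70.0, 0.1), (465.94, 90.0, 0.1), (699.40, 70.0, 0.1),
                (864.15, 90.0, 0.1), (885.75, 100.0, 0.1)]
_PERI_FIXED = [(281.25, 60.0, 0.1), (480.31, 50.0, 0.1), (722.51, 45.0, 0.1),
               (834.53, 60.0, 0.1)]
_CORE_B_EXTRA = [(903.60, 40.0, 0.1), (935.40, 35.0, 0.1)]
_MARGIN_OWN = [(465.94, 60.0, 0.1)]
_FAT_PANEL = [(577.52, 70.0, 0.1), (603.53, 55.0, 0.1), (829.70, 45.0, 0.1)]


def _random_peaks(rng, n: int, amp_range, window: MassWindow | None = None,
                  cv: float = 0.1) -> list:
    lo, hi = (window.low, window.high) if window else (200.0, 1000.0)
    mzs = np.round(rng.uniform(lo + 1, hi - 1, size=n), 2)
    amps = rng.uniform(*amp_range, size=n)
    return [(float(m), float(a), cv) for m, a in zip(mzs, amps)]


def phantom_spec(mode: str = "negative", seed: int = 0,
                 preset: str = "distinct_margin",
                 contrast_by_window: dict | None = None,
                 width: int = 40, height: int = 40,
                 noise_sd: float | None = None,
                 n_random_common: int = 14,
                 n_random_discriminant: int = 2,
                 case_rng: np.random.Generator | None = None) -> PhantomSpec:
    """Build a phantom spec for one of the named tissue-structure presets.

    ``distinct_margin``: the margin band carries its own panel (dominant
    465.94 Da) on top of a tumor/peritumor mixture — the scenario where
    the margin is a spectral class of its own.  ``gradient_margin``: the
    margin is a pure tumor/peritumor mixture.  ``complex`` adds a fat
    region.  Positive mode is noisier than negative (5.0 vs 1.0 intensity
    units of additive noise) unless overridden.
    """
    if contrast_by_window is None:
        contrast_by_window = dict(FULL_CONTRAST)
    if noise_sd is None:
        noise_sd = 5.0 if mode == "positive" else 1.0
    rng = case_rng if case_rng is not None else np.random.default_rng(seed)

    common = list(_COMMON_FIXED) + _random_peaks(rng, n_random_common, (30.0, 90.0))
    tumor_disc = list(_TUMOR_FIXED)
    peri_disc = list(_PERI_FIXED)
    for w in CANONICAL_WINDOWS:
        tumor_disc += _random_peaks(rng, n_random_discriminant, (40.0, 80.0), w)
        peri_disc += _random_peaks(rng, n_random_discriminant, (40.0, 80.0), w)
    tumor_disc = _scale_by_window(tumor_disc, contrast_by_window)
    peri_disc = _scale_by_window(peri_disc, contrast_by_window)
    half = lambda peaks: [(m, a / 2, cv) for m, a, cv in peaks]  # noqa: E731

    cx = width * 0.62 + rng.integers(-2, 3)
    cy = height * 0.62 + rng.integers(-2, 3)
    rx = width * 0.25 + rng.integers(-1, 2)
    ry = height * 0.23 + rng.integers(-1, 2)
    band = 2.0

    # every region-differential peak obeys the window contrast, so zero
    # contrast really means chemically indistinguishable regions
    margin_panel = half(tumor_disc) + half(peri_disc)
    if preset == "distinct_margin":
        margin_panel = margin_panel + _scale_by_window(_MARGIN_OWN, contrast_by_window)
    elif preset not in ("gradient_margin", "complex"):
        raise ValueError(f"unknown preset {preset!r}")
    core_b_extra = _scale_by_window(_CORE_B_EXTRA, contrast_by_window)

    regions = [
        RegionSpec("peritumor", {"kind": "full"}, common + peri_disc),
        RegionSpec("margin_band",
                   {"kind": "ellipse", "cx": cx, "cy": cy,
                    "rx": rx + band, "ry": ry + band},
                   common + margin_panel),
        RegionSpec("tumor_core_a",
                   {"kind": "ellipse", "cx": cx, "cy": cy, "rx": rx, "ry": ry},
                   common + tumor_disc),
        RegionSpec("tumor_core_b",
                   {"kind": "ellipse", "cx": cx + rx * 0.35, "cy": cy + ry * 0.3,
                    "rx": rx * 0.4, "ry": ry * 0.4},
                   common + tumor_disc + core_b_extra),
    ]
    if preset == "complex":
        regions.append(RegionSpec(
            "fat", {"kind": "disk", "cx": width * 0.15, "cy": height * 0.82,
                    "r": min(width, height) * 0.1},
            common + half(peri_disc) + _FAT_PANEL))
    return PhantomSpec(width=width, height=height, regions=regions,
                       noise_sd=noise_sd, mode=mode,
                       seed=int(rng.integers(0, 2**31 - 1)) if case_rng is not None else seed)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _auto_rois(region_labels: np.ndarray, region_names: list) -> ROISet:
    """Place two tumor and two peritumor disk ROIs well inside their regions.

    Each ROI is a radius-2 disk around a deep interior point (maximum of
    the distance transform, and the interior point farthest from it), so
    ROIs never touch the margin band.
    """
    def two_rois(mask: np.ndarray, role: str, prefix: str):
        interior = ndimage.binary_erosion(mask, iterations=2)
        if not interior.any():
            interior = ndimage.binary_erosion(mask)
        if not interior.any():
            raise ValueError(f"region for {role} ROIs too small")
        dt = ndimage.distance_transform_edt(mask)
        dt[~interior] = 0
        p1 = np.unravel_index(int(np.argmax(dt)), mask.shape)
        yy, xx = np.nonzero(interior)
        d2 = (yy - p1[0]) ** 2 + (xx - p1[1]) ** 2
        p2 = (int(yy[np.argmax(d2)]), int(xx[np.argmax(d2)]))
        rois = []
        for i, (py, px) in enumerate((p1, p2)):
            y, x = np.mgrid[0:mask.shape[0], 0:mask.shape[1]]
            disk = ((y - py) ** 2 + (x - px) ** 2 <= 4) & interior
            rois.append(ROI(f"{prefix}{i + 1}", role, disk))
        return rois

    names = region_names
    tumor_mask = np.isin(region_labels,
                         [i for i, n in enumerate(names) if n.startswith("tumor_core")])
    peri_mask = region_labels == names.index("peritumor")
    return ROISet(two_rois(tumor_mask, "tumor", "T")
                  + two_rois(peri_mask, "peritumor", "PT"))


def make_phantom(spec: PhantomSpec) -> tuple:
    """Generate a phantom cube and its ground truth, deterministic per seed.

    Per pixel: sum of region peaks (Gaussian shape, sigma 0.05 Da, on the
    bin grid) x per-pixel lognormal amplitude draw x lognormal TIC-drift
    factor, plus folded-Gaussian additive noise on every bin.
    """
    w, h = spec.width, spec.height
    region_labels = np.full((h, w), -1, dtype=np.int32)
    for i, region in enumerate(spec.regions):
        region_labels[region.mask(w, h)] = i
    if np.any(region_labels < 0):
        raise ValueError("regions do not cover every pixel")

    rng = np.random.default_rng(spec.seed)
    n_bins = int(np.ceil((spec.mass_range.high - spec.mass_range.low) / spec.bin_width))
    centers = spec.mass_range.low + (np.arange(n_bins) + 0.5) * spec.bin_width

    ys, xs = np.nonzero(region_labels >= 0)
    coords = np.column_stack([xs, ys]).astype(np.intp)
    pix_region = region_labels[ys, xs]
    n_pix = coords.shape[0]
    signal = np.zeros((n_pix, n_bins), dtype=np.float64)

    for i, region in enumerate(spec.regions):
        members = np.flatnonzero(pix_region == i)
        if members.size == 0:
            continue
        if region.baseline > 0:
            signal[members] += region.baseline
        for mz, amp, cv in region.peaks:
            lo = np.searchsorted(centers, mz - 4 * PEAK_SIGMA_DA)
            hi = np.searchsorted(centers, mz + 4 * PEAK_SIGMA_DA)
            if hi <= lo:
                continue
            shape = np.exp(-((centers[lo:hi] - mz) ** 2) / (2 * PEAK_SIGMA_DA ** 2))
            s = np.sqrt(np.log1p(cv ** 2))
            draws = amp * rng.lognormal(mean=-s * s / 2, sigma=s, size=members.size)
            signal[members, lo:hi] += np.outer(draws, shape)

    if spec.tic_drift_cv > 0:
        s = np.sqrt(np.log1p(spec.tic_drift_cv ** 2))
        drift = rng.lognormal(mean=-s * s / 2, sigma=s, size=n_pix)
        signal *= drift[:, None]
    if spec.noise_sd > 0:
        noise = np.abs(rng.normal(0.0, spec.noise_sd, size=(n_pix, n_bins)))
        signal += noise

    cube = MSIDataCube(
        width=w, height=h, pixel_coords=coords, mz_axis=centers,
        intensities=signal.astype(np.float32), mode=spec.mode,
        provenance=[f"make_phantom(seed={spec.seed}, mode={spec.mode}, "
                    f"{len(spec.regions)} regions, noise_sd={spec.noise_sd})"],
    )
    names = [r.name for r in spec.regions]
    truth = PhantomTruth(region_labels=region_labels, region_names=names,
                         spec=spec, rois=_auto_rois(region_labels, names))
    return cube, truth


# ---------------------------------------------------------------------------
# case collections
# ---------------------------------------------------------------------------

@dataclass
class PhantomCase:
    case_id: str
    cubes_by_mode: dict  # mode -> MSIDataCube
    truth: PhantomTruth


def iter_case_collection(n_cases: int = 10,
                         contrast_by_window: dict | None = None,
                         seed: int = 0, preset: str = "distinct_margin",
                         width: int = 40, height: int = 40,
                         modes=("negative", "positive")):
    """Yield ground-truthed cases one at a time (memory-friendly).

    Each case draws its own peak-panel variation (random compounds on top
    of the fixed anchors) and geometry jitter from a per-case substream of
    the master seed, emulating the strong interindividual variability of
    real tissue.  Both ionization-mode cubes of a case share geometry and
    panels, differing in noise level and noise realization.
    """
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    if contrast_by_window is None:
        contrast_by_window = dict(DEFAULT_CONTRAST)
    master = np.random.SeedSequence(seed)
    for ci, case_ss in enumerate(master.spawn(n_cases)):
        children = case_ss.spawn(len(modes) + 1)
        cubes = {}
        truth = None
        for mode, child in zip(modes, children[1:]):
            # both modes share the panel/geometry substream (children[0]),
            # so a case's two cubes describe the same tissue; the noise
            # realization comes from the mode's own substream
            panel_rng = np.random.default_rng(children[0])
            spec = phantom_spec(mode=mode, preset=preset,
                                contrast_by_window=contrast_by_window,
                                width=width, height=height,
                                case_rng=panel_rng)
            spec.seed = int(np.random.default_rng(child).integers(0, 2**31 - 1))
            cube, truth = make_phantom(spec)
            cubes[mode] = cube
        yield PhantomCase(case_id=f"case{ci + 1:02d}", cubes_by_mode=cubes,
                          truth=truth)


def make_case_collection(n_cases: int = 10,
                         contrast_by_window: dict | None = None,
                         seed: int = 0, **kw) -> list:
    """Materialized list form of :func:`iter_case_collection`."""
    return list(iter_case_collection(n_cases=n_cases,
                                     contrast_by_window=contrast_by_window,
                                     seed=seed, **kw))


# ---------------------------------------------------------------------------
# fixture suite
# ---------------------------------------------------------------------------

def _content_checksum(cube: MSIDataCube) -> str:
    """SHA-256 over the cube's canonical content (not file bytes: imzML
    embeds a fresh UUID on every write, so raw files are never identical)."""
    hsh = hashlib.sha256()
    hsh.update(np.ascontiguousarray(cube.pixel_coords).tobytes())
    hsh.update(np.ascontiguousarray(cube.mz_axis).tobytes())
    hsh.update(np.ascontiguousarray(cube.intensities).tobytes())
    hsh.update(cube.mode.encode())
    return hsh.hexdigest()


def write_fixture_suite(directory: str | Path, seed: int = 20260101,
                        n_cases: int = 3, width: int = 24, height: int = 24) -> dict:
    """Emit a small fixed-seed fixture set: imzML pairs + truth/ROI JSON.

    Returns (and writes) a manifest with per-cube content checksums; a
    rerun with the same seed reproduces identical checksums.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": seed, "cases": []}
    for case in iter_case_collection(n_cases=n_cases, seed=seed,
                                     width=width, height=height):
        entry = {"case_id": case.case_id, "files": {}, "checksums": {}}
        for mode, cube in case.cubes_by_mode.items():
            stem = f"{case.case_id}_{mode}"
            write_imzml(cube, directory / f"{stem}.imzML")
            entry["files"][mode] = f"{stem}.imzML"
            entry["checksums"][mode] = _content_checksum(cube)
        truth_file = directory / f"{case.case_id}_truth.json"
        truth_file.write_text(json.dumps({
            "region_names": case.truth.region_names,
            "region_labels": case.truth.region_labels.tolist(),
        }))
        case.truth.rois.to_json(directory / f"{case.case_id}_rois.json")
        entry["files"]["truth"] = truth_file.name
        entry["files"]["rois"] = f"{case.case_id}_rois.json"
        manifest["cases"].append(entry)
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
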