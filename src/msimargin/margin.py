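"""Tumor-margin recognition statistics and image information content.

The margin-recognition rule operates on a segmented image and four
pathologist-style regions of interest (ROIs): two over the tumor, two over
the peritumor.  The tumor's reference cluster is the modal label over the
tumor ROIs; the margin is deemed correctly localized when strictly less
than 10% of peritumor-ROI pixels carry that label.  Over a case
collection, agreement with the histology gold standard is scored by an
exact one-sided binomial test against chance (p0 = 1/2).

Image information content is measured as the byte size of the segmented
label image after lossless PNG compression; trends of that size across
mass windows are tested by ordinary least squares with t-tests on the
slope (one-sided, for a decrease) and on the between-mode slope
difference (interaction term).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction
from math import comb
from pathlib import Path

import numpy as np
from scipy import stats as sstats

from .datacube import DEFAULT_PALETTE, NO_TISSUE, LabelMap, Palette, render_png
from .preprocess import CANONICAL_WINDOWS

__all__ = [
    "ROI",
    "ROISet",
    "MarginAssessment",
    "RecognitionSummary",
    "InfoContentRecord",
    "tumor_reference_label",
    "peritumor_match_pct",
    "assess_margin",
    "recognition_binomial_test",
    "info_content",
    "trend_tests",
    "assess_case",
    "CaseReport",
]

DEFAULT_THRESHOLD_PCT = 10.0


# ---------------------------------------------------------------------------
# ROIs
# ---------------------------------------------------------------------------

@dataclass
class ROI:
    name: str
    role: str  # "tumor" | "peritumor"
    mask: np.ndarray  # bool (height, width)

    def __post_init__(self) -> None:
        if self.role not in ("tumor", "peritumor"):
            raise ValueError(f"ROI role must be tumor/peritumor, got {self.role!r}")
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError(f"ROI {self.name!r} is empty")


@dataclass
class ROISet:
    """Exactly four ROIs on one grid: two tumor, two peritumor."""

    rois: list[ROI]

    def __post_init__(self) -> None:
        roles = sorted(r.role for r in self.rois)
        if roles != ["peritumor", "peritumor", "tumor", "tumor"]:
            raise ValueError("an ROISet needs exactly two tumor and two peritumor ROIs")
        shapes = {r.mask.shape for r in self.rois}
        if len(shapes) != 1:
            raise ValueError("all ROI masks must share one grid shape")

    def union(self, role: str) -> np.ndarray:
        masks = [r.mask for r in self.rois if r.role == role]
        return np.logical_or.reduce(masks)

    # -- JSON interchange: named polygons or run-length masks with roles --
    def to_json(self, path: str | Path | None = None) -> str:
        entries = []
        for r in self.rois:
            ys, xs = np.nonzero(r.mask)
            runs = []
            for y in np.unique(ys):
                row = np.sort(xs[ys == y])
                breaks = np.flatnonzero(np.diff(row) > 1)
                starts = np.concatenate(([0], breaks + 1))
                ends = np.concatenate((breaks, [row.size - 1]))
                for s, e in zip(starts, ends):
                    runs.append([int(y), int(row[s]), int(row[e] - row[s] + 1)])
            entries.append({"name": r.name, "role": r.role, "type": "rle",
                            "shape": list(r.mask.shape), "runs": runs})
        text = json.dumps(entries, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ROISet":
        text = Path(source).read_text() if isinstance(source, Path) or (
            isinstance(source, str) and source.lstrip()[:1] not in "[{") else source
        entries = json.loads(text)
        rois = []
        for e in entries:
            shape = tuple(e["shape"])
            mask = np.zeros(shape, dtype=bool)
            if e.get("type", "rle") == "rle":
                for y, x0, length in e["runs"]:
                    mask[y, x0:x0 + length] = True
            elif e["type"] == "polygon":
                from PIL import Image, ImageDraw
                img = Image.new("L", (shape[1], shape[0]), 0)
                ImageDraw.Draw(img).polygon(
                    [tuple(p) for p in e["vertices"]], outline=1, fill=1)
                mask = np.asarray(img, dtype=bool)
            else:
                raise ValueError(f"unknown ROI encoding {e['type']!r}")
            rois.append(ROI(e["name"], e["role"], mask))
        return cls(rois)


# ---------------------------------------------------------------------------
# the margin statistic
# ---------------------------------------------------------------------------

def tumor_reference_label(label_map: LabelMap, rois: ROISet) -> int:
    """Modal cluster label over the union of the two tumor ROIs.

    Ties go to the smaller label.  NO_TISSUE positions are ignored.
    """
    union = rois.union("tumor")
    labels = label_map.labels[union]
    labels = labels[labels != NO_TISSUE]
    if labels.size == 0:
        raise ValueError("tumor ROIs do not overlap any tissue pixel")
    counts = np.bincount(labels, minlength=label_map.k)
    return int(np.argmax(counts))  # argmax -> first max -> smallest label


def peritumor_match_pct(label_map: LabelMap, rois: ROISet, tumor_label: int,
                        pooled: bool = True):
    """Percentage of peritumor-ROI pixels carrying the tumor's label.

    With ``pooled=True`` (default) the two peritumor ROIs are merged into
    one count; otherwise a per-ROI list of percentages is returned.
    """
    def pct(mask: np.ndarray) -> float:
        labels = label_map.labels[mask]
        labels = labels[labels != NO_TISSUE]
        if labels.size == 0:
            raise ValueError("no valid (tissue) pixels in peritumor ROI")
        return 100.0 * float((labels == tumor_label).sum()) / labels.size

    if pooled:
        return pct(rois.union("peritumor"))
    return [pct(r.mask) for r in rois.rois if r.role == "peritumor"]


@dataclass(frozen=True)
class MarginAssessment:
    """Margin-recognition verdict for one (mode, window, k) combination."""

    tumor_label: int
    match_pct: float
    recognized: bool
    threshold: float = DEFAULT_THRESHOLD_PCT
    window: str | None = None
    mode: str | None = None
    k: int | None = None
    advisory: bool = False  # True for k != 2, where matching is unreliable

    def __post_init__(self) -> None:
        if self.recognized != (self.match_pct < self.threshold):
            raise ValueError("recognized flag inconsistent with match_pct < threshold")


def assess_margin(label_map: LabelMap, rois: ROISet,
                  threshold: float = DEFAULT_THRESHOLD_PCT,
                  window: str | None = None, mode: str | None = None,
                  k: int | None = None) -> MarginAssessment:
    """Apply the strict <threshold% margin-recognition rule to one map."""
    t = tumor_reference_label(label_map, rois)
    pct = peritumor_match_pct(label_map, rois, t)
    return MarginAssessment(
        tumor_label=t, match_pct=pct, recognized=bool(pct < threshold),
        threshold=threshold, window=window, mode=mode, k=k,
        advisory=(k is not None and k != 2),
    )


# ---------------------------------------------------------------------------
# exact binomial inference
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RecognitionSummary:
    successes: int
    trials: int
    p_value: float

    @property
    def rate(self) -> float:
        return self.successes / self.trials


def recognition_binomial_test(successes: int, trials: int) -> RecognitionSummary:
    """Exact one-sided binomial upper tail under chance p0 = 1/2.

    P(X >= s | n, 1/2) = sum_{i>=s} C(n, i) / 2^n, computed in exact
    integer arithmetic before the final float conversion.
    """
    if trials < 1 or not 0 <= successes <= trials:
        raise ValueError("need 0 <= successes <= trials and trials >= 1")
    tail = Fraction(sum(comb(trials, i) for i in range(successes, trials + 1)),
                    2 ** trials)
    return RecognitionSummary(successes=successes, trials=trials,
                              p_value=float(tail))


# ---------------------------------------------------------------------------
# information content
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InfoContentRecord:
    """Compressed size of a segmented image, the information-content proxy."""

    case_id: str
    mode: str | None
    k: int
    window: str | None
    bytes: int

    def __post_init__(self) -> None:
        if self.bytes <= 0:
            raise ValueError("PNG byte count must be positive")

    @property
    def kb(self) -> float:
        # reported in KiB (1024 bytes); raw bytes are always preserved
        return self.bytes / 1024.0


def info_content(label_map: LabelMap, palette: Palette = DEFAULT_PALETTE,
                 case_id: str = "", mode: str | None = None,
                 k: int | None = None, window: str | None = None) -> InfoContentRecord:
    """PNG byte size of a label map under the pinned encoder settings."""
    nbytes = render_png(label_map, palette)
    return InfoContentRecord(case_id=case_id, mode=mode,
                             k=k if k is not None else label_map.k,
                             window=window, bytes=nbytes)


# ---------------------------------------------------------------------------
# trend tests on information content
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModeTrend:
    mode: str
    slope: float          # KiB per window step
    p_decreasing: float   # one-sided t-test of slope < 0
    n_obs: int


@dataclass(frozen=True)
class SlopeDifference:
    modes: tuple
    difference: float
    p_value: float        # two-sided t-test on the interaction term


@dataclass(frozen=True)
class TrendTestResult:
    per_mode: dict
    slope_difference: SlopeDifference | None


def _window_index(labels: list[str]) -> dict[str, int]:
    lows = {w: float(str(w).split("-")[0]) for w in set(labels)}
    ordered = sorted(lows, key=lows.get)
    return {w: i + 1 for i, w in enumerate(ordered)}


def _ols_slope_test(x: np.ndarray, y: np.ndarray):
    """Slope, one-sided p (slope<0) via OLS; exact-fit degenerate cases handled."""
    import statsmodels.api as sm

    X = sm.add_constant(x.astype(float))
    fit = sm.OLS(y.astype(float), X).fit()
    slope = float(fit.params[1])
    if fit.df_resid <= 0 or fit.ssr < 1e-20:
        # perfectly collinear data: the t statistic degenerates; report the
        # machine-limit verdict rather than NaN
        p = 0.0 if slope < 0 else 1.0
        return slope, p, fit
    t = float(fit.tvalues[1])
    p = float(sstats.t.cdf(t, fit.df_resid))
    return slope, p, fit


def trend_tests(records, regressor: str = "index") -> TrendTestResult:
    """Test per-mode information-content trends across mass windows.

    Pools records within each mode and regresses size (KiB) on the window
    index 1..4 (or the window's m/z midpoint with ``regressor="midpoint"``).
    Reports the per-mode slope with a one-sided t-test for a decreasing
    trend, and, when two modes are present, a two-sided t-test of the
    between-mode slope difference through the interaction term of a joint
    regression.
    """
    records = list(records)
    if not records:
        raise ValueError("no records")
    windows = [r.window for r in records]
    if len(set(windows)) < 2:
        raise ValueError("trend tests need at least two mass windows")
    if regressor == "index":
        idx = _window_index(windows)
        xval = {w: float(i) for w, i in idx.items()}
    elif regressor == "midpoint":
        xval = {w: (float(str(w).split("-")[0]) + float(str(w).split("-")[1])) / 2
                for w in set(windows)}
    else:
        raise ValueError(f"unknown regressor {regressor!r}")

    per_mode = {}
    modes = sorted({r.mode for r in records}, key=str)
    for m in modes:
        sub = [r for r in records if r.mode == m]
        if len(sub) < 2:
            continue
        x = np.array([xval[r.window] for r in sub])
        y = np.array([r.kb for r in sub])
        slope, p, _ = _ols_slope_test(x, y)
        per_mode[m] = ModeTrend(mode=str(m), slope=slope, p_decreasing=p, n_obs=len(sub))

    diff = None
    if len(modes) == 2:
        import statsmodels.api as sm

        x = np.array([xval[r.window] for r in records], dtype=float)
        d = np.array([1.0 if r.mode == modes[1] else 0.0 for r in records])
        y = np.array([r.kb for r in records])
        X = np.column_stack([np.ones_like(x), x, d, x * d])
        fit = sm.OLS(y, X).fit()
        delta = float(fit.params[3])
        if fit.df_resid <= 0 or fit.ssr < 1e-20:
            p = 0.0 if delta != 0 else 1.0
        else:
            p = float(fit.pvalues[3])
        diff = SlopeDifference(modes=tuple(map(str, modes)), difference=delta, p_value=p)
    return TrendTestResult(per_mode=per_mode, slope_difference=diff)


# ---------------------------------------------------------------------------
# per-case assembly
# ---------------------------------------------------------------------------

@dataclass
class CaseRow:
    mode: str
    window: str
    k: int
    margin: MarginAssessment | None
    info: InfoContentRecord
    heterogeneity_index: int  # distinct cluster labels inside the tumor ROIs
    dominant_margin_mz: float | None = None

    def to_dict(self) -> dict:
        d = {"mode": self.mode, "window": self.window, "k": self.k,
             "bytes": self.info.bytes, "kb": self.info.kb,
             "heterogeneity_index": self.heterogeneity_index,
             "dominant_margin_mz": self.dominant_margin_mz}
        if self.margin is not None:
            d.update(tumor_label=self.margin.tumor_label,
                     match_pct=self.margin.match_pct,
                     recognized=self.margin.recognized,
                     advisory=self.margin.advisory)
        return d


@dataclass
class CaseReport:
    case_id: str
    rows: list = field(default_factory=list)
    gaps: list = field(default_factory=list)  # (mode, window, reason)

    def to_dict(self) -> dict:
        return {"case_id": self.case_id,
                "rows": [r.to_dict() for r in self.rows],
                "gaps": self.gaps}

    def row(self, mode: str, window: str, k: int) -> CaseRow:
        for r in self.rows:
            if (r.mode, r.window, r.k) == (mode, window, k):
                return r
        raise KeyError((mode, window, k))


def assess_case(cubes_by_mode: dict, rois: ROISet,
                k_values=(2, 10), windows=CANONICAL_WINDOWS,
                threshold: float = DEFAULT_THRESHOLD_PCT,
                case_id: str = "case", palette: Palette = DEFAULT_PALETTE,
                png_dir: str | Path | None = None,
                normalize: bool = True) -> CaseReport:
    """Run the full per-case factorial: mode x mass window x cluster count.

    For every combination the cube is TIC-normalized on the full range,
    windowed, segmented, and scored: the margin assessment (authoritative
    for k=2, advisory otherwise), the PNG information-content record, and
    a heterogeneity index (distinct denary labels inside the tumor ROIs).
    Missing or failing combinations are reported as gaps rather than
    aborting the case.
    """
    from .preprocess import tic_normalize, window_mass_range
    from .segmentation import dominant_mz, hca_segment_multi

    report = CaseReport(case_id=case_id)
    tumor_union = rois.union("tumor")
    for mode, cube in sorted(cubes_by_mode.items()):
        norm = tic_normalize(cube) if normalize else cube
        for w in windows:
            try:
                wcube = window_mass_range(norm, w)
                results = hca_segment_multi(wcube, k_values)
            except Exception as exc:  # noqa: BLE001 - per-case isolation
                report.gaps.append((mode, w.label, f"{type(exc).__name__}: {exc}"))
                continue
            for k in sorted(results):
                res = results[k]
                margin = assess_margin(res.label_map, rois, threshold=threshold,
                                       window=w.label, mode=mode, k=k)
                info = info_content(res.label_map, palette, case_id=case_id,
                                    mode=mode, k=k, window=w.label)
                t_labels = res.label_map.labels[tumor_union]
                t_labels = t_labels[t_labels != NO_TISSUE]
                hetero = int(np.unique(t_labels).size)
                dom = None
                # the margin-adjacent cluster summary: dominant m/z of the
                # smallest non-tumor cluster's mean spectrum (k=2: the
                # non-tumor class; descriptive output only)
                try:
                    other = [c for c in range(k) if c != margin.tumor_label]
                    if other:
                        c = other[-1]
                        dom = dominant_mz(res.mean_spectra[c], wcube.mz_axis, c).mz
                except ValueError:
                    dom = None
                if png_dir is not None:
                    png_dir = Path(png_dir)
                    png_dir.mkdir(parents=True, exist_ok=True)
                    render_png(res.label_map, palette,
                               png_dir / f"{case_id}_{mode}_{w.label}_k{k}.png")
                report.rows.append(CaseRow(mode=mode, window=w.label, k=k,
                                           margin=margin, info=info,
                                           heterogeneity_index=hetero,
                                           dominant_margin_mz=dom))
    return report
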