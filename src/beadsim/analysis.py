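"""Bead isolation and pixel-intensity analysis of dark-background well images.

Pipeline (forward of what the imaging platform records): grayscale
conversion -> optional histogram equalization (needed to pull nearly
transparent beads out of the background) -> global threshold -> morphological
clean-up -> connected-component selection, yielding a binary bead mask.
Intensity statistics are always computed on the *raw* grayscale restricted
to that mask, on the 8-bit 0-255 scale; equalization only ever influences
where the mask is, never the reported numbers.

On top of the per-frame analysis sit the two study-level assemblies: the
concentration-screen summary table and the per-well time series with a
change-point + exponential-decay fit of disintegration kinetics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import OptimizeWarning, curve_fit
from skimage import measure, morphology
from skimage.filters import threshold_otsu

__all__ = [
    "SegmentationConfig",
    "BeadMask",
    "IntensityResult",
    "WellTimeSeries",
    "DisintegrationFit",
    "FitConfig",
    "FormatError",
    "MeasurementError",
    "AnalysisError",
    "to_gray",
    "enhance_contrast",
    "segment_bead",
    "measure_intensity",
    "summarize_screen",
    "analyze_timelapse",
]

# ITU-R BT.601 luminance weights for RGB -> gray.
_GRAY_WEIGHTS = np.array([0.299, 0.587, 0.114])


class FormatError(ValueError):
    """Input image has the wrong shape or dtype."""


class MeasurementError(ValueError):
    """Intensity requested where no bead was found."""


class AnalysisError(ValueError):
    """A series-level analysis cannot proceed (too few usable frames)."""


def to_gray(frame: np.ndarray) -> np.ndarray:
    """8-bit luminance image from an (H, W, 3) uint8 frame.

    gray = round(0.299 R + 0.587 G + 0.114 B); equal channels map to
    themselves exactly.
    """
    frame = np.asarray(frame)
    if frame.ndim != 3 or frame.shape[2] != 3:
        raise FormatError(f"expected (H, W, 3) frame, got shape {frame.shape}")
    gray = frame.astype(np.float64) @ _GRAY_WEIGHTS
    return np.clip(np.rint(gray), 0, 255).astype(np.uint8)


def enhance_contrast(img: np.ndarray) -> np.ndarray:
    """Global histogram equalization of an 8-bit image.

    Classic cumulative-histogram mapping
    ``out(v) = round(255 * (cdf(v) - cdf_min) / (N - cdf_min))`` where
    ``cdf_min`` is the cdf at the lowest occupied level.  Rank order of
    distinct values is preserved and the dynamic range never shrinks.
    A constant image is returned unchanged (degenerate histogram).
    """
    img = np.asarray(img)
    if img.ndim != 2:
        raise FormatError(f"expected single-channel image, got shape {img.shape}")
    img = img.astype(np.uint8)
    hist = np.bincount(img.ravel(), minlength=256)
    cdf = np.cumsum(hist)
    occupied = np.nonzero(hist)[0]
    if occupied.size <= 1:
        return img.copy()
    cdf_min = cdf[occupied[0]]
    n = img.size
    lut = np.rint(255.0 * (cdf - cdf_min) / (n - cdf_min)).astype(np.uint8)
    return lut[img]


@dataclass(frozen=True)
class SegmentationConfig:
    """Controls for :func:`segment_bead`.

    ``equalize``: 'auto' equalizes only when the grayscale dynamic range
    (p99 - p1) is below ``contrast_trigger`` levels, mirroring the fact
    that equalization is required for transparent beads but unnecessary for
    opaque ones.  After optional equalization the same range gate is applied
    again: an image whose range still sits below the trigger has no
    distinguishable bead and yields found=False rather than a noise mask.
    """

    equalize: str = "auto"  # auto | always | never
    contrast_trigger: float = 40.0  # 8-bit levels
    threshold_method: str = "otsu"  # otsu | fixed
    fixed_threshold: Optional[int] = None
    min_area: int = 500  # px; smallest credible bead at 640x480 (~13 px radius)
    morph_radius: int = 2  # px
    center_bias: bool = True

    def __post_init__(self):
        if self.equalize not in ("auto", "always", "never"):
            raise ValueError("equalize must be auto|always|never")
        if self.threshold_method not in ("otsu", "fixed"):
            raise ValueError("threshold_method must be otsu|fixed")
        if (self.threshold_method == "fixed") != (self.fixed_threshold is not None):
            raise ValueError("fixed_threshold required iff threshold_method='fixed'")


@dataclass
class BeadMask:
    mask: np.ndarray  # bool, frame-sized
    found: bool
    area: int
    centroid: Optional[tuple[float, float]]  # (x, y) px

    @classmethod
    def empty(cls, shape: tuple[int, int]) -> "BeadMask":
        return cls(np.zeros(shape, dtype=bool), False, 0, None)


def _dynamic_range(gray: np.ndarray) -> float:
    p1, p99 = np.percentile(gray, [1, 99])
    return float(p99 - p1)


def segment_bead(frame: np.ndarray, cfg: SegmentationConfig = SegmentationConfig()) -> BeadMask:
    """Isolate the bead in a frame as a single-component binary mask.

    Absence of a bead is a result (found=False), never an error.  The mask
    is in original-frame coordinates.
    """
    gray = to_gray(frame)
    work = gray
    if cfg.equalize == "always" or (
        cfg.equalize == "auto" and _dynamic_range(gray) < cfg.contrast_trigger
    ):
        work = enhance_contrast(gray)
    # contrast gate: a near-flat image cannot be thresholded meaningfully
    if _dynamic_range(work) < cfg.contrast_trigger:
        return BeadMask.empty(gray.shape)
    if cfg.threshold_method == "fixed":
        thr = float(cfg.fixed_threshold)
    else:
        if work.min() == work.max():
            return BeadMask.empty(gray.shape)
        thr = float(threshold_otsu(work))
    binary = work > thr
    if cfg.morph_radius > 0:
        footprint = morphology.disk(cfg.morph_radius)
        binary = morphology.opening(binary, footprint)
        binary = morphology.closing(binary, footprint)
    labels = measure.label(binary, connectivity=2)
    regions = [r for r in measure.regionprops(labels) if r.area >= cfg.min_area]
    if not regions:
        return BeadMask.empty(gray.shape)
    if cfg.center_bias:
        cy0, cx0 = (gray.shape[0] - 1) / 2.0, (gray.shape[1] - 1) / 2.0
        best = min(regions, key=lambda r: (r.centroid[0] - cy0) ** 2 + (r.centroid[1] - cx0) ** 2)
    else:
        best = max(regions, key=lambda r: r.area)
    mask = labels == best.label
    cy, cx = best.centroid
    return BeadMask(mask, True, int(best.area), (float(cx), float(cy)))


@dataclass(frozen=True)
class IntensityResult:
    mean: float
    sd: float
    n_pixels: int
    quantiles: tuple[float, float, float, float, float]  # p5, p25, p50, p75, p95


def measure_intensity(frame: np.ndarray, mask: BeadMask) -> IntensityResult:
    """Pixel-intensity statistics (0-255) of the raw grayscale under the mask.

    Always measured on the non-equalized image: the opacity interpretation
    of the 8-bit scale only holds for raw counts.
    """
    if not mask.found:
        raise MeasurementError("no bead: mask.found is False")
    gray = to_gray(frame)
    if mask.mask.shape != gray.shape:
        raise FormatError("mask and frame dimensions differ")
    vals = gray[mask.mask].astype(np.float64)
    q = np.percentile(vals, [5, 25, 50, 75, 95])
    return IntensityResult(
        mean=float(vals.mean()),
        sd=float(vals.std()),
        n_pixels=int(vals.size),
        quantiles=tuple(float(x) for x in q),
    )


# ---------------------------------------------------------------------------
# Screen summary

def summarize_screen(records: Sequence, cfg: SegmentationConfig = SegmentationConfig()) -> pd.DataFrame:
    """Analyze a rendered concentration screen end to end.

    ``records`` holds objects with ``alginate_pct``, ``cacl2_pct`` and
    ``frame`` attributes (e.g. :class:`beadsim.synth.ScreenRecord`).
    One row per condition; conditions where no bead is found are kept with
    found=False and NaN statistics rather than zeros.
    """
    if not records:
        raise ValueError("empty screen grid")
    rows = []
    for rec in records:
        mask = segment_bead(rec.frame, cfg)
        row = {
            "alginate_pct": rec.alginate_pct,
            "cacl2_pct": rec.cacl2_pct,
            "found": mask.found,
            "mean": np.nan,
            "sd": np.nan,
            "n_pixels": 0,
            "p5": np.nan, "p25": np.nan, "p50": np.nan, "p75": np.nan, "p95": np.nan,
        }
        if mask.found:
            res = measure_intensity(rec.frame, mask)
            row.update(
                mean=res.mean, sd=res.sd, n_pixels=res.n_pixels,
                p5=res.quantiles[0], p25=res.quantiles[1], p50=res.quantiles[2],
                p75=res.quantiles[3], p95=res.quantiles[4],
            )
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Time series + kinetics

@dataclass
class WellTimeSeries:
    well: str
    times: list[float] = field(default_factory=list)
    results: list[Optional[IntensityResult]] = field(default_factory=list)

    def append(self, t: float, result: Optional[IntensityResult]) -> None:
        if self.times and t <= self.times[-1]:
            raise ValueError("times must be strictly increasing")
        self.times.append(t)
        self.results.append(result)

    def found_points(self) -> tuple[np.ndarray, np.ndarray]:
        t = [t for t, r in zip(self.times, self.results) if r is not None]
        y = [r.mean for r in self.results if r is not None]
        return np.asarray(t, dtype=float), np.asarray(y, dtype=float)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for t, r in zip(self.times, self.results):
            rows.append({
                "t": t,
                "found": r is not None,
                "mean": r.mean if r else np.nan,
                "sd": r.sd if r else np.nan,
                "n_pixels": r.n_pixels if r else 0,
            })
        return pd.DataFrame(rows)


@dataclass
class DisintegrationFit:
    onset_found: bool
    onset_t: Optional[float] = None
    k_decay_hat: Optional[float] = None
    baseline_hat: Optional[float] = None
    amplitude_hat: Optional[float] = None
    rss: Optional[float] = None


@dataclass(frozen=True)
class FitConfig:
    """Change-point fit controls.

    The onset is found by an exhaustive two-segment scan: every admissible
    split is scored by (saturating-rise fit of the head) + (exponential-decay
    fit of the tail); the split with minimal total residual wins.  A split is
    accepted only when it beats the single-segment rise fit by
    ``improvement_factor`` (RSS ratio), otherwise onset_found=False.
    """

    min_segment: int = 2  # points per segment
    improvement_factor: float = 0.5


def _fit_rise(t: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """Least-squares saturating rise  y = P + (B - P) exp(-k t); returns (fit, rss)."""
    if len(t) == 1:
        return y.copy(), 0.0
    p0 = [float(y.max()), float(y[0]), max(1.0 / (t[-1] - t[0] + 1e-9), 1e-4)]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", OptimizeWarning)
            popt, _ = curve_fit(
                lambda tt, P, B, k: P + (B - P) * np.exp(-k * tt),
                t, y, p0=p0, maxfev=5000,
                bounds=([0.0, 0.0, 1e-7], [300.0, 300.0, 10.0]),
            )
        fit = popt[0] + (popt[1] - popt[0]) * np.exp(-popt[2] * t)
    except Exception:
        coef = np.polyfit(t, y, 1) if len(t) > 2 else np.array([0.0, float(y.mean())])
        fit = np.polyval(coef, t)
    return fit, float(np.sum((y - fit) ** 2))


def _fit_decay(t: np.ndarray, y: np.ndarray, t0: float) -> tuple[Optional[tuple], float]:
    """Least-squares  y = b + A exp(-k (t - t0)); returns ((b, A, k), rss)."""
    if len(t) < 2:
        return None, float("inf")
    b0 = float(y.min())
    a0 = max(float(y[0] - b0), 1e-3)
    span = t[-1] - t[0] + 1e-9
    p0 = [b0, a0, 2.0 / span]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", OptimizeWarning)
            popt, _ = curve_fit(
                lambda tt, b, A, k: b + A * np.exp(-k * (tt - t0)),
                t, y, p0=p0, maxfev=5000,
                bounds=([0.0, 0.0, 1e-7], [300.0, 300.0, 10.0]),
            )
    except Exception:
        return None, float("inf")
    fit = popt[0] + popt[1] * np.exp(-popt[2] * (t - t0))
    return tuple(float(v) for v in popt), float(np.sum((y - fit) ** 2))


def fit_disintegration(
    times: np.ndarray, means: np.ndarray, cfg: FitConfig = FitConfig()
) -> DisintegrationFit:
    """Change-point + kinetics fit of a mean-intensity trajectory."""
    t = np.asarray(times, dtype=float)
    y = np.asarray(means, dtype=float)
    if len(t) < 4:
        raise AnalysisError("kinetic fitting needs at least 4 time points")
    _, rss_single = _fit_rise(t, y)
    best = None  # (total_rss, onset_idx, decay_params)
    for i in range(cfg.min_segment, len(t) - cfg.min_segment + 1):
        _, rss_head = _fit_rise(t[:i], y[:i])
        params, rss_tail = _fit_decay(t[i:], y[i:], t[i])
        if params is None or params[2] <= 1e-6:
            continue
        total = rss_head + rss_tail
        if best is None or total < best[0]:
            best = (total, i, params)
    if best is None or best[0] > cfg.improvement_factor * max(rss_single, 1e-12):
        return DisintegrationFit(onset_found=False)
    total, i, (b, a, k) = best
    return DisintegrationFit(
        onset_found=True,
        onset_t=float(t[i]),
        k_decay_hat=k,
        baseline_hat=b,
        amplitude_hat=a,
        rss=total,
    )


def analyze_timelapse(
    series: Sequence,
    cfg: SegmentationConfig = SegmentationConfig(),
    fit_cfg: FitConfig = FitConfig(),
    well: str = "A1",
) -> tuple[WellTimeSeries, DisintegrationFit]:
    """Per-frame segmentation + measurement, then a disintegration fit.

    ``series`` holds objects with ``t`` and ``frame`` attributes (e.g.
    :class:`beadsim.synth.TimelapseRecord`).
    """
    ts = WellTimeSeries(well=well)
    for rec in series:
        mask = segment_bead(rec.frame, cfg)
        ts.append(rec.t, measure_intensity(rec.frame, mask) if mask.found else None)
    t, y = ts.found_points()
    if len(t) == 0:
        raise AnalysisError("no frame contained a detectable bead")
    if len(t) < 4:
        raise AnalysisError("kinetic fitting needs at least 4 usable time points")
    return ts, fit_disintegration(t, y, fit_cfg)
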