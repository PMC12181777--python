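"""Synthetic well imaging: phenomenological bead opacity + frame renderer.

Ground truth generator for the analysis pipeline.  A well holds at most one
roughly circular calcium-alginate bead on a dark background; its opacity is
driven by two phenomenological models:

* **Gelation**: opacity is unimodal in the crosslinker-to-polymer mass-percent
  ratio R = CaCl2% / alginate%.  Sparse crosslinking leaves the bead nearly
  transparent; past a critical ratio ``r_crit`` over-crosslinking (syneresis,
  shrinkage) makes beads translucent again.  The bump is a two-sided
  log-Gaussian in R: continuous, strictly increasing below ``r_crit`` and
  strictly decreasing above it, with separate rise/fall widths.

* **Disintegration**: before chelator (EDTA) addition the opacity rises
  saturating from ``baseline_opacity`` toward ``plateau_opacity`` with rate
  ``k_rise``; from ``t_edta`` on it relaxes exponentially back toward the
  baseline with rate ``k_decay`` (calcium sequestration dissolving the
  network).  The curve is continuous at ``t_edta``.

The renderer maps opacity linearly onto the 8-bit scale (disk level
``round(bg + opacity * (255 - bg))``), applies an optional disk-mean blur to
soften the bead edge, adds clipped zero-mean Gaussian noise, and is
bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "GelationParams",
    "DisintegrationParams",
    "WellScene",
    "CameraModel",
    "RenderError",
    "SCREEN_ALGINATE_PCT",
    "SCREEN_CACL2_PCT",
    "opacity_from_concentrations",
    "opacity_time_course",
    "render_frame",
    "simulate_screen",
    "simulate_timelapse",
    "ScreenRecord",
    "TimelapseRecord",
]

# Default concentration grid of the reference screen (%w/v).
SCREEN_ALGINATE_PCT = (0.5, 1.0, 1.5, 2.0)
SCREEN_CACL2_PCT = (0.1, 0.5, 1.0, 1.5, 5.0, 10.0)


class RenderError(ValueError):
    """Scene geometry cannot be rendered (bead outside the frame)."""


@dataclass(frozen=True)
class GelationParams:
    """Crosslinking-vs-opacity model parameters.

    ``r_crit`` is placed so that at 1.5 % alginate the opacity peaks near
    1.5 % CaCl2 (the observed turnover between 1.5 % and 5 %), i.e. at
    R = 1.  ``rise_scale``/``fall_scale`` are the log-R widths of the bump
    below/above the peak; the rise side is steeper, so starved-crosslinker
    beads are fainter than equally mis-ratioed over-crosslinked ones.
    ``visibility_floor`` marks the opacity below which a bead is effectively
    impossible to see against the background.
    """

    alginate_pct: float = 1.5
    cacl2_pct: float = 1.0
    r_crit: float = 1.0
    rise_scale: float = 0.5
    fall_scale: float = 1.1
    peak_opacity: float = 0.9
    visibility_floor: float = 0.15

    def __post_init__(self):
        if self.r_crit <= 0:
            raise ValueError("r_crit must be > 0")
        if not (0.0 <= self.peak_opacity <= 1.0):
            raise ValueError("peak_opacity must lie in [0, 1]")


def opacity_from_concentrations(g: GelationParams) -> float:
    """Bead opacity in [0, 1] from the concentration pair in ``g``.

    opacity(R) = peak * exp(-(ln(R / r_crit))^2 / (2 s^2)), with
    s = rise_scale for R < r_crit and fall_scale above.  Unimodal with its
    maximum ``peak_opacity`` exactly at R = r_crit.
    """
    if g.alginate_pct <= 0 or g.cacl2_pct <= 0:
        raise ValueError("concentrations must be > 0")
    r = g.cacl2_pct / g.alginate_pct
    z = math.log(r / g.r_crit)
    s = g.rise_scale if z < 0 else g.fall_scale
    return g.peak_opacity * math.exp(-(z * z) / (2.0 * s * s))


@dataclass(frozen=True)
class DisintegrationParams:
    """Opacity time-course parameters (rates in 1/s, times in s)."""

    t_edta: Optional[float] = 300.0
    k_decay: float = 0.01
    k_rise: float = 0.003
    baseline_opacity: float = 0.1
    plateau_opacity: float = 0.85

    def __post_init__(self):
        if self.t_edta is not None and self.k_decay <= 0:
            raise ValueError("k_decay must be > 0 when t_edta is set")
        if self.baseline_opacity > self.plateau_opacity:
            raise ValueError("baseline_opacity must not exceed plateau_opacity")


def opacity_time_course(d: DisintegrationParams, t: float) -> float:
    """True bead opacity at time ``t`` (s) since gel formation.

    Saturating rise baseline -> plateau with rate ``k_rise``; from
    ``t_edta`` on, exponential relaxation back toward the baseline with
    rate ``k_decay``.  Continuous at ``t_edta``.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    b, p = d.baseline_opacity, d.plateau_opacity

    def rising(tt: float) -> float:
        return p + (b - p) * math.exp(-d.k_rise * tt)

    if d.t_edta is None or t < d.t_edta:
        return rising(t)
    o_edta = rising(d.t_edta)
    return b + (o_edta - b) * math.exp(-d.k_decay * (t - d.t_edta))


@dataclass(frozen=True)
class WellScene:
    """Ground-truth state of one well at one instant."""

    bead_present: bool = True
    opacity: float = 0.8
    radius: float = 100.0  # px
    center_offset: tuple[float, float] = (0.0, 0.0)  # (dx, dy) px from centre
    background_level: int = 6  # 8-bit counts

    def __post_init__(self):
        if not (0.0 <= self.opacity <= 1.0):
            raise ValueError("opacity must lie in [0, 1]")
        if not (0 <= self.background_level <= 255):
            raise ValueError("background_level must lie in 0-255")


@dataclass(frozen=True)
class CameraModel:
    """Virtual 8-bit RGB camera; equal seeds give bit-identical frames."""

    width: int = 640
    height: int = 480
    noise_sigma: float = 3.0  # counts
    blur_radius: int = 2  # px, disk-mean kernel; 0 disables
    seed: int = 0


def _disk_mask(h: int, w: int, cy: float, cx: float, radius: float) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2


def true_bead_mask(scene: WellScene, cam: CameraModel) -> np.ndarray:
    """Boolean ground-truth disk mask for a scene under a camera geometry."""
    if not scene.bead_present:
        return np.zeros((cam.height, cam.width), dtype=bool)
    cy = cam.height / 2.0 + scene.center_offset[1]
    cx = cam.width / 2.0 + scene.center_offset[0]
    return _disk_mask(cam.height, cam.width, cy, cx, scene.radius)


def render_frame(scene: WellScene, cam: CameraModel) -> np.ndarray:
    """Render a scene to an (H, W, 3) uint8 RGB frame.

    Pre-noise disk level is round(bg + opacity * (255 - bg)); outside the
    disk, the background level.  Then the optional disk-mean blur, per-channel
    additive Gaussian noise from the camera seed, and clipping to 0-255.
    """
    h, w = cam.height, cam.width
    bg = float(scene.background_level)
    img = np.full((h, w), bg, dtype=np.float64)
    if scene.bead_present:
        cy = h / 2.0 + scene.center_offset[1]
        cx = w / 2.0 + scene.center_offset[0]
        if (cy - scene.radius < 0 or cy + scene.radius > h
                or cx - scene.radius < 0 or cx + scene.radius > w):
            raise RenderError("bead disk extends outside the frame")
        level = round(bg + scene.opacity * (255.0 - bg))
        img[_disk_mask(h, w, cy, cx, scene.radius)] = level
    if cam.blur_radius > 0:
        r = cam.blur_radius
        yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
        kernel = (yy**2 + xx**2 <= r**2).astype(np.float64)
        kernel /= kernel.sum()
        img = ndimage.convolve(img, kernel, mode="nearest")
    rgb = np.repeat(img[:, :, None], 3, axis=2)
    if cam.noise_sigma > 0:
        rng = np.random.default_rng(cam.seed)
        rgb = rgb + rng.normal(0.0, cam.noise_sigma, size=rgb.shape)
    return np.clip(np.rint(rgb), 0, 255).astype(np.uint8)


@dataclass(frozen=True)
class ScreenRecord:
    alginate_pct: float
    cacl2_pct: float
    scene: WellScene
    frame: np.ndarray


@dataclass(frozen=True)
class TimelapseRecord:
    t: float
    scene: WellScene
    frame: np.ndarray


def simulate_screen(
    alginate_list: Sequence[float] = SCREEN_ALGINATE_PCT,
    cacl2_list: Sequence[float] = SCREEN_CACL2_PCT,
    gelation: GelationParams = GelationParams(),
    cam: CameraModel = CameraModel(),
    t_capture: float = 1800.0,
    maturation_rate: float = 0.003,
    scene_template: WellScene = WellScene(),
) -> list[ScreenRecord]:
    """Render the concentration screen: one frame per (alginate, CaCl2) pair.

    Each condition's opacity is the gelation-model value attenuated by the
    maturation factor ``1 - exp(-maturation_rate * t_capture)`` (at the
    default 30 min capture the gel is essentially fully matured).  Per-frame
    seeds are spawned deterministically from ``cam.seed``.
    """
    if not alginate_list or not cacl2_list:
        raise ValueError("concentration lists must be non-empty")
    maturation = 1.0 - math.exp(-maturation_rate * t_capture)
    seeds = np.random.SeedSequence(cam.seed).generate_state(
        len(alginate_list) * len(cacl2_list)
    )
    out: list[ScreenRecord] = []
    k = 0
    for alg in alginate_list:
        for ca in cacl2_list:
            g = replace(gelation, alginate_pct=alg, cacl2_pct=ca)
            opacity = opacity_from_concentrations(g) * maturation
            scene = replace(scene_template, bead_present=True, opacity=opacity)
            frame = render_frame(scene, replace(cam, seed=int(seeds[k])))
            out.append(ScreenRecord(alg, ca, scene, frame))
            k += 1
    return out


def simulate_timelapse(
    d: DisintegrationParams = DisintegrationParams(),
    schedule: Sequence[float] = (),
    cam: CameraModel = CameraModel(),
    scene_template: WellScene = WellScene(),
) -> list[TimelapseRecord]:
    """Render one well's frames at each schedule time (strictly increasing).

    Ground truth follows :func:`opacity_time_course`; per-frame seeds are
    spawned from ``cam.seed`` so a rerun with the same camera is
    bit-identical.
    """
    times = list(schedule)
    if any(b <= a for a, b in zip(times, times[1:])):
        raise ValueError("schedule must be strictly increasing")
    if not times:
        return []
    seeds = np.random.SeedSequence(cam.seed).generate_state(len(times))
    out: list[TimelapseRecord] = []
    for i, t in enumerate(times):
        scene = replace(scene_template, opacity=opacity_time_course(d, t))
        frame = render_frame(scene, replace(cam, seed=int(seeds[i])))
        out.append(TimelapseRecord(float(t), scene, frame))
    return out
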