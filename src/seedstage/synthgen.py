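"""Synthetic top-view tray time-lapse generator.

Emulates the imaging setup the rest of the package is built for: trays of
soil-filled pots photographed from above at a 15-minute cadence during a 16-h
photoperiod (night frames are never produced; wall-clock timestamps carry the
gaps).  Each tray carries five white fiducial landmarks (center + four
corners) and a ``grid_rows x grid_cols`` grid of pots.  Every pot follows a
known stage schedule Soil -> FA -> OC -> FL, rendered as simple parametric
green shapes on brown soil:

* FA — a single small closed blob (cotyledon just out of the soil),
* OC — two separated cotyledon lobes,
* FL — the two lobes plus a central third lobe (the first true leaf).

The shapes are deliberately schematic, not photorealistic: the point is a
fully known ground truth (per-pot transition frames) so that landmark
detection, rectification, classifier training and event-timing recovery can
all be scored exactly.  A ``difficulty`` knob shrinks lobe separation and
overlaps stage-size distributions to emulate the genuinely hard OC/FL
boundary of real seedlings; ``NoiseSpec`` adds circadian lobe movement,
neighbour-pot overlap and degenerate (barely visible) renderings, the error
sources observed on real trays.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
from skimage.color import hsv2rgb
from skimage.transform import rotate as _sk_rotate
import imageio.v3 as iio

from .errors import ConfigurationError, GeometryError
from .stages import StageLabel

__all__ = [
    "NoiseSpec",
    "SceneConfig",
    "StageSchedule",
    "SyntheticDataset",
    "sample_stage_schedule",
    "render_tray_frame",
    "build_truth_table",
    "generate_dataset",
    "rotate_point",
]

#: Shape parameters per difficulty level.  Radii in px; ``lobe_sep`` is the
#: centre-to-centre distance of the two cotyledon lobes; ``size_jitter`` the
#: relative per-pot spread of all radii (this is what blurs the OC/FL border).
_DIFFICULTY = {
    "easy": dict(fa_r=3.5, oc_r=6.0, fl_r=5.5, lobe_sep=15.0, size_jitter=0.05),
    "medium": dict(fa_r=3.5, oc_r=5.5, fl_r=3.5, lobe_sep=10.0, size_jitter=0.15),
    "hard": dict(fa_r=4.0, oc_r=5.0, fl_r=2.5, lobe_sep=7.0, size_jitter=0.25),
}

_SOIL_HSV = (20.0 / 360.0, 0.50, 0.45)   # brown
_PLANT_HUE_DEG = 100.0                   # green, jittered per pot
_BENCH_VALUE = 0.12                      # dark background outside the tray


@dataclasses.dataclass(frozen=True)
class NoiseSpec:
    """Stochastic nuisance effects of real tray time-lapses.

    circadian_jitter_px
        Amplitude (px) of the periodic day/night displacement of plant lobes
        (period 24 h, per-pot phase) — the circadian movement that perturbs
        frame classification near stage boundaries.
    overlap_prob
        Probability that a germinated pot grows an extra lobe extending into
        a neighbouring pot once it reaches OC.
    flip_prob
        Per-(pot, frame) probability that the rendering is degenerate (a tiny
        blob regardless of true stage), emulating occlusion/annotation noise.
    pixel_noise_sd
        Additive Gaussian RGB noise, in 8-bit counts.
    """

    circadian_jitter_px: float = 1.5
    overlap_prob: float = 0.0
    flip_prob: float = 0.0
    pixel_noise_sd: float = 2.0

    def __post_init__(self):
        for name in ("overlap_prob", "flip_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {p}")
        if self.circadian_jitter_px < 0 or self.pixel_noise_sd < 0:
            raise ConfigurationError("amplitudes must be >= 0")


@dataclasses.dataclass(frozen=True)
class SceneConfig:
    """Geometry, cadence and noise of one synthetic experiment."""

    n_trays: int = 1
    grid_rows: int = 10
    grid_cols: int = 20
    pot_size_px: int = 89
    frames_total: int = 768
    interval_min: float = 15.0
    photoperiod_h: float = 16.0
    landmark_radius_px: float = 6.0
    margin_px: int = 40
    tray_rotation_deg: float = 0.0
    difficulty: str = "easy"
    noise: NoiseSpec = dataclasses.field(default_factory=NoiseSpec)
    seed: int = 0
    start: str = "2026-03-01T08:00:00"

    def __post_init__(self):
        if self.grid_rows * self.grid_cols < 1:
            raise ConfigurationError("grid must contain at least one pot")
        if self.frames_total < 1:
            raise ConfigurationError("frames_total must be >= 1")
        if self.interval_min <= 0:
            raise ConfigurationError("interval_min must be > 0")
        if not -45.0 < self.tray_rotation_deg <= 45.0:
            raise ConfigurationError("tray_rotation_deg must lie in (-45, 45]")
        if self.difficulty not in _DIFFICULTY:
            raise ConfigurationError(
                f"difficulty must be one of {sorted(_DIFFICULTY)}")
        if self.pot_size_px < 8:
            raise ConfigurationError("pot_size_px too small to draw a plant")

    # -- derived geometry -------------------------------------------------
    @property
    def grid_shape_px(self) -> tuple[int, int]:
        return (self.grid_rows * self.pot_size_px,
                self.grid_cols * self.pot_size_px)

    @property
    def canvas_shape(self) -> tuple[int, int]:
        gh, gw = self.grid_shape_px
        return (gh + 2 * self.margin_px, gw + 2 * self.margin_px)

    @property
    def frames_per_day(self) -> int:
        return max(1, int(round(self.photoperiod_h * 60.0 / self.interval_min)))

    def landmark_positions(self, rotated: bool = True) -> dict[str, tuple[float, float]]:
        """(x, y) centres of the five landmarks, optionally after rotation."""
        m = float(self.margin_px)
        gh, gw = (float(v) for v in self.grid_shape_px)
        pts = {
            "TL": (m, m), "TR": (m + gw, m),
            "BL": (m, m + gh), "BR": (m + gw, m + gh),
            "C": (m + gw / 2.0, m + gh / 2.0),
        }
        if rotated and self.tray_rotation_deg != 0.0:
            h, w = self.canvas_shape
            center = ((w - 1) / 2.0, (h - 1) / 2.0)
            pts = {k: rotate_point(v, center, self.tray_rotation_deg)
                   for k, v in pts.items()}
        return pts

    def timestamp(self, frame_index: int) -> _dt.datetime:
        """Wall-clock time of a kept (daytime) frame; nights are skipped."""
        fpd = self.frames_per_day
        day, slot = divmod(int(frame_index), fpd)
        t0 = _dt.datetime.fromisoformat(self.start)
        return t0 + _dt.timedelta(days=day, minutes=slot * self.interval_min)


def rotate_point(xy, center, angle_deg: float) -> tuple[float, float]:
    """Forward point map of ``skimage.transform.rotate(img, angle_deg)``.

    skimage rotates the raster counter-clockwise on screen; with x right and
    y down that is the matrix [[c, s], [-s, c]] about the image centre.
    """
    th = np.deg2rad(angle_deg)
    c, s = np.cos(th), np.sin(th)
    x, y = xy[0] - center[0], xy[1] - center[1]
    return (center[0] + x * c + y * s, center[1] - x * s + y * c)


# ---------------------------------------------------------------------------
# Stage schedules
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class StageSchedule:
    """Per-pot ground-truth transition frames; ``-1`` means "never".

    Arrays are shaped ``(n_trays, grid_rows, grid_cols)``.  For germinated
    pots ``t_fa < t_oc < t_fl`` always holds (transitions may exceed
    ``frames_total`` — the stage is then simply never observed).
    """

    t_fa: np.ndarray
    t_oc: np.ndarray
    t_fl: np.ndarray

    def __post_init__(self):
        germ = self.t_fa >= 0
        if not (np.all(self.t_fa[germ] < self.t_oc[germ])
                and np.all(self.t_oc[germ] < self.t_fl[germ])):
            raise ConfigurationError("schedule must satisfy t_FA < t_OC < t_FL")
        if not np.all((self.t_oc[~germ] == -1) & (self.t_fl[~germ] == -1)):
            raise ConfigurationError("non-germinated pots must be 'never' throughout")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.t_fa.shape

    def labels(self, tray: int, row: int, col: int, frames_total: int) -> np.ndarray:
        """Stage code per frame for one pot (non-decreasing by construction)."""
        f = np.arange(frames_total)
        out = np.zeros(frames_total, dtype=np.int64)
        for t, code in ((self.t_fa[tray, row, col], StageLabel.FA),
                        (self.t_oc[tray, row, col], StageLabel.OC),
                        (self.t_fl[tray, row, col], StageLabel.FL)):
            if t >= 0:
                out[f >= t] = int(code)
        return out

    def label_array(self, frames_total: int) -> np.ndarray:
        """All labels, shaped (n_trays, rows, cols, frames_total)."""
        nt, nr, nc = self.shape
        f = np.arange(frames_total)[None, None, None, :]
        out = np.zeros((nt, nr, nc, frames_total), dtype=np.int64)
        for t, code in ((self.t_fa, StageLabel.FA), (self.t_oc, StageLabel.OC),
                        (self.t_fl, StageLabel.FL)):
            tt = t[..., None]
            out[(tt >= 0) & (f >= tt)] = int(code)
        return out


#: Default transition-delay distributions, as fractions of ``frames_total``.
#: Uniform windows sized so a typical germinated pot traverses all four
#: stages within the recorded two weeks, with broad pot-to-pot spread.
DEFAULT_DELAY_PARAMS = {
    "t_fa_range": (0.15, 0.40),   # emergence frame
    "fa_dur_range": (0.08, 0.18),  # FA -> OC delay
    "oc_dur_range": (0.18, 0.35),  # OC -> FL delay
}


def sample_stage_schedule(config: SceneConfig,
                          germination_prob: float = 0.9,
                          delay_params: dict | None = None,
                          ) -> StageSchedule:
    """Draw per-pot transition frames.

    With probability ``1 - germination_prob`` a pot never germinates and is
    Soil for the whole sequence.  Delays are drawn uniformly from the ranges
    in ``delay_params`` (fractions of ``frames_total``; see
    ``DEFAULT_DELAY_PARAMS``).  Deterministic given ``config.seed``.
    """
    if not 0.0 <= germination_prob <= 1.0:
        raise ConfigurationError("germination_prob must be in [0, 1]")
    p = dict(DEFAULT_DELAY_PARAMS, **(delay_params or {}))
    for key in ("t_fa_range", "fa_dur_range", "oc_dur_range"):
        lo, hi = p[key]
        if lo < 0 or hi < lo or (key != "t_fa_range" and hi <= 0):
            raise ConfigurationError(f"{key} must have positive support, got {p[key]}")

    rng = np.random.default_rng([config.seed, 101])
    shape = (config.n_trays, config.grid_rows, config.grid_cols)
    T = config.frames_total
    germ = rng.random(shape) < germination_prob
    t_fa = np.rint(rng.uniform(*p["t_fa_range"], shape) * T).astype(np.int64)
    fa_d = np.maximum(1, np.rint(rng.uniform(*p["fa_dur_range"], shape) * T)).astype(np.int64)
    oc_d = np.maximum(1, np.rint(rng.uniform(*p["oc_dur_range"], shape) * T)).astype(np.int64)
    t_oc = t_fa + fa_d
    t_fl = t_oc + oc_d
    for arr in (t_fa, t_oc, t_fl):
        arr[~germ] = -1
    return StageSchedule(t_fa=t_fa, t_oc=t_oc, t_fl=t_fl)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _pot_appearance(config: SceneConfig, tray: int, row: int, col: int) -> dict:
    """Per-pot deterministic appearance parameters (radii, axis, phase)."""
    d = _DIFFICULTY[config.difficulty]
    rng = np.random.default_rng([config.seed, 202, tray, row, col])
    j = d["size_jitter"]
    scale = float(np.exp(rng.normal(0.0, j)))
    return {
        "fa_r": d["fa_r"] * scale,
        "oc_r": d["oc_r"] * scale,
        "fl_r": d["fl_r"] * scale,
        "lobe_sep": d["lobe_sep"] * scale,
        "axis_deg": float(rng.uniform(0.0, 180.0)),
        "phase": float(rng.uniform(0.0, 2 * np.pi)),
        "jitter_dir_deg": float(rng.uniform(0.0, 360.0)),
        "hue_deg": _PLANT_HUE_DEG + float(rng.uniform(-8.0, 8.0)),
        "overlap": bool(rng.random() < config.noise.overlap_prob),
        "offset": rng.uniform(-2.0, 2.0, size=2),
    }


def _ellipse_alpha(yy, xx, cx, cy, rx, ry, angle_deg):
    """Anti-aliased ellipse coverage in [0, 1] (~1 px soft edge)."""
    th = np.deg2rad(angle_deg)
    dx, dy = xx - cx, yy - cy
    u = dx * np.cos(th) + dy * np.sin(th)
    v = -dx * np.sin(th) + dy * np.cos(th)
    q = np.sqrt((u / rx) ** 2 + (v / ry) ** 2)
    # approximate signed pixel distance to the boundary
    d = (1.0 - q) * min(rx, ry)
    return np.clip(d + 0.5, 0.0, 1.0)


def _plant_lobes(stage: int, app: dict, jitter_xy, degenerate: bool):
    """List of (cx, cy, rx, ry, angle) ellipse lobes in pot-local coords
    (origin at pot centre)."""
    jx, jy = jitter_xy
    ox, oy = app["offset"]
    cx, cy = ox + jx, oy + jy
    if degenerate:
        return [(cx, cy, 1.2, 1.0, 0.0)]
    a = app["axis_deg"]
    th = np.deg2rad(a)
    ux, uy = np.cos(th), np.sin(th)
    half = app["lobe_sep"] / 2.0
    lobes = []
    if stage == StageLabel.FA:
        lobes.append((cx, cy, app["fa_r"] * 1.2, app["fa_r"], a))
    elif stage >= StageLabel.OC:
        r = app["oc_r"]
        lobes.append((cx - ux * half, cy - uy * half, r, 0.75 * r, a))
        lobes.append((cx + ux * half, cy + uy * half, r, 0.75 * r, a))
        if stage == StageLabel.FL:
            # first leaf emerges between the cotyledons, offset from the axis
            off = app["fl_r"] * 0.9
            lobes.append((cx - uy * off, cy + ux * off,
                          app["fl_r"] * 1.3, app["fl_r"] * 0.8, a + 90.0))
    return lobes


def _soil_texture(config: SceneConfig, tray: int) -> np.ndarray:
    """Static per-tray soil texture in [0, 1] RGB, full canvas."""
    from scipy.ndimage import gaussian_filter

    h, w = config.canvas_shape
    rng = np.random.default_rng([config.seed, 303, tray])
    base = np.array(hsv2rgb(np.array(_SOIL_HSV)[None, None, :]))[0, 0]
    img = np.empty((h, w, 3), dtype=np.float64)
    img[:] = base
    # correlation lengths sit above the bilinear-interpolation kernel so the
    # texture survives the rectification resampling nearly unchanged
    blotch = gaussian_filter(rng.normal(0.0, 1.0, (h, w)), 4.0)
    blotch = 0.05 * blotch / max(blotch.std(), 1e-9)
    speck = gaussian_filter(rng.normal(0.0, 1.0, (h, w)), 2.0)
    speck = 0.01 * speck / max(speck.std(), 1e-9)
    img += (blotch + speck)[:, :, None]
    # pot rims: darker 1-px lines on the pot grid, the periodic structure
    # that anchors Fourier-based orientation estimation
    m0, s0 = config.margin_px, config.pot_size_px
    for r in range(config.grid_rows + 1):
        y = min(m0 + r * s0, h - 1)
        img[y, m0:m0 + config.grid_cols * s0] *= 0.55
    for c in range(config.grid_cols + 1):
        x = min(m0 + c * s0, w - 1)
        img[m0:m0 + config.grid_rows * s0, x] *= 0.55
    # bench area outside the tray border
    m = config.margin_px
    border = max(2, m // 4)
    bench = np.ones((h, w), dtype=bool)
    bench[m - border:h - m + border, m - border:w - m + border] = False
    img[bench] = _BENCH_VALUE
    return np.clip(img, 0.0, 1.0)


_TEXTURE_CACHE: dict[tuple, np.ndarray] = {}


def render_tray_frame(config: SceneConfig, schedule: StageSchedule,
                      frame_index: int, tray: int = 0,
                      return_mask: bool = False):
    """Render one tray frame as an 8-bit RGB array.

    Soil-textured tray with five white landmark discs, per-pot plant shapes
    according to the schedule, circadian jitter, optional whole-tray rotation.
    Deterministic given ``config.seed`` and ``frame_index``.  With
    ``return_mask=True`` also returns the boolean plant mask (same geometry,
    nearest-neighbour rotated).
    """
    if frame_index >= config.frames_total or frame_index < 0:
        raise GeometryError(f"frame_index {frame_index} out of range")
    h, w = config.canvas_shape
    s = config.pot_size_px
    if config.grid_rows * s > h or config.grid_cols * s > w:
        raise GeometryError("pot grid larger than canvas")

    key = (config, tray)
    tex = _TEXTURE_CACHE.get(key)
    if tex is None:
        tex = _soil_texture(config, tray)
        _TEXTURE_CACHE.clear()
        _TEXTURE_CACHE[key] = tex
    img = tex.copy()
    mask = np.zeros((h, w), dtype=bool)

    hours = (config.timestamp(frame_index) -
             _dt.datetime.fromisoformat(config.start)).total_seconds() / 3600.0
    m = config.margin_px
    flip_rng = np.random.default_rng([config.seed, 404, tray, frame_index])
    yy, xx = np.mgrid[0:s, 0:s].astype(np.float64)
    for r in range(config.grid_rows):
        for c in range(config.grid_cols):
            stage = _stage_at(schedule, tray, r, c, frame_index)
            if stage == StageLabel.SOIL:
                # still consume the flip draw to keep the stream aligned
                flip_rng.random()
                continue
            app = _pot_appearance(config, tray, r, c)
            degenerate = flip_rng.random() < config.noise.flip_prob
            amp = config.noise.circadian_jitter_px
            ang = 2 * np.pi * hours / 24.0 + app["phase"]
            jd = np.deg2rad(app["jitter_dir_deg"])
            jitter = (amp * np.sin(ang) * np.cos(jd), amp * np.sin(ang) * np.sin(jd))
            lobes = _plant_lobes(int(stage), app, jitter, degenerate)
            if app["overlap"] and stage >= StageLabel.OC and not degenerate:
                th = np.deg2rad(app["axis_deg"])
                reach = s * 0.55
                lobes.append((np.cos(th) * reach, np.sin(th) * reach,
                              app["oc_r"], 0.6 * app["oc_r"], app["axis_deg"]))
            alpha = np.zeros((s, s), dtype=np.float64)
            cx0, cy0 = (s - 1) / 2.0, (s - 1) / 2.0
            for (lx, ly, rx, ry, a) in lobes:
                alpha = np.maximum(
                    alpha, _ellipse_alpha(yy, xx, cx0 + lx, cy0 + ly, rx, ry, a))
            y0, x0 = m + r * s, m + c * s
            hue = app["hue_deg"] / 360.0
            val = 0.70 if stage == StageLabel.FL else 0.55
            green = hsv2rgb(np.array([hue, 0.85, val])[None, None, :])[0, 0]
            region = img[y0:y0 + s, x0:x0 + s]
            region[:] = (1.0 - alpha[:, :, None]) * region + alpha[:, :, None] * green
            mask[y0:y0 + s, x0:x0 + s] |= alpha > 0.5

    # landmarks drawn last so nothing occludes them
    yy_c, xx_c = np.mgrid[0:h, 0:w]
    for (lx, ly) in config.landmark_positions(rotated=False).values():
        disc = (xx_c - lx) ** 2 + (yy_c - ly) ** 2 <= config.landmark_radius_px ** 2
        img[disc] = 1.0

    if config.tray_rotation_deg != 0.0:
        img = _sk_rotate(img, config.tray_rotation_deg, resize=False,
                         cval=_BENCH_VALUE, order=1, preserve_range=True)
        if return_mask:
            mask = _sk_rotate(mask.astype(float), config.tray_rotation_deg,
                              resize=False, cval=0.0, order=0,
                              preserve_range=True) > 0.5

    noise_rng = np.random.default_rng([config.seed, 505, tray, frame_index])
    if config.noise.pixel_noise_sd > 0:
        img = img + noise_rng.normal(0.0, config.noise.pixel_noise_sd / 255.0,
                                     img.shape)
    out = (np.clip(img, 0.0, 1.0) * 255.0).round().astype(np.uint8)
    return (out, mask) if return_mask else out


def _stage_at(schedule: StageSchedule, tray, row, col, frame) -> int:
    if schedule.t_fl[tray, row, col] >= 0 and frame >= schedule.t_fl[tray, row, col]:
        return int(StageLabel.FL)
    if schedule.t_oc[tray, row, col] >= 0 and frame >= schedule.t_oc[tray, row, col]:
        return int(StageLabel.OC)
    if schedule.t_fa[tray, row, col] >= 0 and frame >= schedule.t_fa[tray, row, col]:
        return int(StageLabel.FA)
    return int(StageLabel.SOIL)


def plant_mask(config: SceneConfig, schedule: StageSchedule, tray: int,
               row: int, col: int, frame_index: int) -> np.ndarray:
    """Ground-truth plant mask of one pot crop (unrotated geometry)."""
    _, full = render_tray_frame(config, schedule, frame_index, tray,
                                return_mask=True)
    s, m = config.pot_size_px, config.margin_px
    y0, x0 = m + row * s, m + col * s
    return full[y0:y0 + s, x0:x0 + s]


# ---------------------------------------------------------------------------
# Dataset assembly
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SyntheticDataset:
    """In-memory handle on a generated experiment."""

    config: SceneConfig
    schedule: StageSchedule
    truth: pd.DataFrame                      # tray,row,col,frame,timestamp_iso,stage
    frame_paths: list[Path] | None = None    # set when rendered to disk

    def iter_frames(self) -> Iterator[tuple[int, int, np.ndarray]]:
        """Yield (tray, frame_index, image), rendering lazily."""
        for tray in range(self.config.n_trays):
            for f in range(self.config.frames_total):
                yield tray, f, render_tray_frame(self.config, self.schedule, f, tray)


def build_truth_table(config: SceneConfig, schedule: StageSchedule) -> pd.DataFrame:
    """Long-format ground truth: one row per (tray, pot, frame).

    Row count is exactly ``n_trays * grid_rows * grid_cols * frames_total``.
    """
    nt, nr, nc = schedule.shape
    T = config.frames_total
    labels = schedule.label_array(T)                       # (nt, nr, nc, T)
    tray, row, col, frame = np.meshgrid(
        np.arange(nt), np.arange(nr), np.arange(nc), np.arange(T), indexing="ij")
    stamps = [config.timestamp(f).isoformat() for f in range(T)]
    df = pd.DataFrame({
        "tray": tray.ravel(), "row": row.ravel(), "col": col.ravel(),
        "frame": frame.ravel(),
        "timestamp_iso": np.asarray(stamps, dtype=object)[frame.ravel()],
        "stage": labels.ravel(),
    })
    return df


def generate_dataset(config: SceneConfig,
                     out_dir: str | Path | None = None,
                     germination_prob: float = 0.9,
                     delay_params: dict | None = None,
                     render: bool = True) -> SyntheticDataset:
    """Sample a schedule, build the truth table and (optionally) write frames.

    Frames are written as ``tray{T}_frame{F:04d}.png`` plus ``truth.csv``
    under ``out_dir``.  Identical seeds give byte-identical outputs.  With
    ``render=False`` only the schedule and truth table are produced (frames
    can still be rendered lazily from the returned handle).
    """
    schedule = sample_stage_schedule(config, germination_prob, delay_params)
    truth = build_truth_table(config, schedule)
    paths: list[Path] | None = None
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        truth.to_csv(out / "truth.csv", index=False)
        if render:
            paths = []
            for tray in range(config.n_trays):
                for f in range(config.frames_total):
                    img = render_tray_frame(config, schedule, f, tray)
                    p = out / f"tray{tray}_frame{f:04d}.png"
                    iio.imwrite(p, img)
                    paths.append(p)
    return SyntheticDataset(config=config, schedule=schedule, truth=truth,
                            frame_paths=paths)
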