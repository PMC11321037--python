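"""Synthetic widefield fields and chromatin-puncta trajectories.

Emulates the statistical structure the staging and mobility analyses
assume, so every downstream stage can be exercised without real
microscopy data:

* multi-channel 16-bit fields containing elliptical nuclei whose
  internal chromatin-like texture coarsens monotonically with a latent
  differentiation time (the learnable signal), plus an actin-fiber
  channel and a low-contrast brightfield composite;
* 2D fractional-Brownian trajectories whose ensemble mean squared
  displacement follows ``CD(tau) = d_eff * tau**beta`` exactly in
  expectation, optionally corrupted by per-frame rigid nuclear motion;
* rendered puncta movies for testing detection and linking.

All generators are pure functions of their parameters, including the
seed; no global random state is touched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

from .segment import FieldImage

DEFAULT_STAGES_H = (0.0, 6.0, 24.0, 48.0, 72.0)

#: 16-bit intensity budget for the nucleus channel.
_NUC_BASE = 12000.0
_NUC_AMPLITUDE = 30000.0


def grain_for_stage(stage_hours: float) -> float:
    """Characteristic chromatin blob size (px) for a differentiation time.

    Strictly monotone in ``stage_hours``. Growth is geometric (1.2 px at
    0 h to 5 px at 72 h), which makes the interior GLCM contrast —
    roughly proportional to 1/grain^2 — log-linearly spaced across the
    five default stages, so each consecutive stage pair is separated by
    a comparable contrast ratio.
    """
    return 1.2 * (5.0 / 1.2) ** (stage_hours / 72.0)


@dataclass(frozen=True)
class StageParams:
    """Parameters for one synthetic field at a given differentiation time."""

    stage_hours: float = 0.0
    n_nuclei: int = 8
    field_shape: tuple[int, int] = (640, 640)
    nucleus_axis_range_px: tuple[float, float] = (27.0, 46.0)
    texture_grain_px: float | None = None  # default: grain_for_stage(stage_hours)
    texture_contrast: float = 1.0
    actin_fiber_density: float = 0.002
    noise_sd: float = 150.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.stage_hours <= 72.0:
            raise ValueError("stage_hours must lie in [0, 72]")
        if self.n_nuclei < 1:
            raise ValueError("n_nuclei must be positive")
        lo, hi = self.nucleus_axis_range_px
        if not 0 < lo <= hi:
            raise ValueError("invalid nucleus_axis_range_px")
        if self.texture_grain_px is not None and self.texture_grain_px <= 0:
            raise ValueError("texture_grain_px must be > 0")
        if not 0 < self.texture_contrast <= 1:
            raise ValueError("texture_contrast must be in (0, 1]")
        if self.noise_sd < 0 or self.actin_fiber_density < 0:
            raise ValueError("noise_sd and actin_fiber_density must be >= 0")

    @property
    def grain_px(self) -> float:
        if self.texture_grain_px is not None:
            return self.texture_grain_px
        return grain_for_stage(self.stage_hours)


@dataclass(frozen=True)
class NucleusRecord:
    """Ground truth for one placed nucleus."""

    nucleus_id: int
    center: tuple[float, float]  # (row, col)
    semi_axes: tuple[float, float]
    angle_rad: float
    bbox: tuple[int, int, int, int]  # row_min, col_min, row_max, col_max (half-open)
    stage_hours: float


class PlacementError(RuntimeError):
    """Raised when non-overlapping nucleus placement fails."""


def _ellipse_mask(shape, center, axes, angle):
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    dr = rr - center[0]
    dc = cc - center[1]
    ca, sa = math.cos(angle), math.sin(angle)
    u = dr * ca + dc * sa
    v = -dr * sa + dc * ca
    return (u / axes[0]) ** 2 + (v / axes[1]) ** 2 <= 1.0


def _ellipse_bbox(center, axes, angle, shape):
    # axis-aligned extent of a rotated ellipse
    a, b = axes
    ca, sa = math.cos(angle), math.sin(angle)
    half_r = math.sqrt((a * ca) ** 2 + (b * sa) ** 2)
    half_c = math.sqrt((a * sa) ** 2 + (b * ca) ** 2)
    r0 = max(0, int(math.floor(center[0] - half_r)))
    c0 = max(0, int(math.floor(center[1] - half_c)))
    r1 = min(shape[0], int(math.ceil(center[0] + half_r)) + 1)
    c1 = min(shape[1], int(math.ceil(center[1] + half_c)) + 1)
    return (r0, c0, r1, c1)


def _place_nuclei(params: StageParams, rng: np.random.Generator) -> list[NucleusRecord]:
    shape = params.field_shape
    lo, hi = params.nucleus_axis_range_px
    records: list[NucleusRecord] = []
    max_retries = 100
    for k in range(params.n_nuclei):
        for attempt in range(max_retries + 1):
            if attempt == max_retries:
                raise PlacementError(
                    f"could not place nucleus {k + 1}/{params.n_nuclei} after "
                    f"{max_retries} retries; nucleus density too high for field "
                    f"shape {shape} with axes in [{lo}, {hi}] px"
                )
            a = rng.uniform(lo, hi)
            b = rng.uniform(lo, hi)
            angle = rng.uniform(0, math.pi)
            margin = max(a, b) + 3
            cr = rng.uniform(margin, shape[0] - margin)
            cc = rng.uniform(margin, shape[1] - margin)
            ok = True
            for rec in records:
                d = math.hypot(cr - rec.center[0], cc - rec.center[1])
                if d < max(a, b) + max(rec.semi_axes) + 4:
                    ok = False
                    break
            if ok:
                bbox = _ellipse_bbox((cr, cc), (a, b), angle, shape)
                records.append(
                    NucleusRecord(
                        nucleus_id=k,
                        center=(cr, cc),
                        semi_axes=(a, b),
                        angle_rad=angle,
                        bbox=bbox,
                        stage_hours=params.stage_hours,
                    )
                )
                break
    return records


def _render_nucleus_texture(canvas, rec, grain_px, contrast, rng):
    r0, c0, r1, c1 = rec.bbox
    sub_shape = (r1 - r0, c1 - c0)
    mask = _ellipse_mask(
        sub_shape, (rec.center[0] - r0, rec.center[1] - c0), rec.semi_axes, rec.angle_rad
    )
    area = int(mask.sum())
    # blob count scales with area / grain^2 so coverage stays comparable
    n_blobs = max(8, int(area / (4.0 * grain_px**2)))
    impulses = np.zeros(sub_shape, dtype=np.float64)
    idx = np.flatnonzero(mask)
    chosen = rng.choice(idx, size=n_blobs, replace=True)
    np.add.at(impulses.ravel(), chosen, 1.0)
    blobs = ndimage.gaussian_filter(impulses, sigma=grain_px, mode="constant")
    # standardize within the nucleus and clip at +-3 sd so the intensity
    # range is stable across grain sizes and the neighboring-pixel
    # correlation (hence GLCM contrast) is a function of grain alone
    mu = blobs[mask].mean()
    sd = blobs[mask].std()
    z = (blobs - mu) / sd if sd > 0 else np.zeros_like(blobs)
    u = np.clip(0.5 + z / 6.0, 0.0, 1.0)
    patch = mask * (_NUC_BASE + contrast * _NUC_AMPLITUDE * u)
    canvas[r0:r1, c0:c1] = np.maximum(canvas[r0:r1, c0:c1], patch)


def _render_actin(shape, records, density, rng):
    """Oriented fiber strokes around and across nuclei."""
    canvas = np.zeros(shape, dtype=np.float64)
    n_fibers = int(density * shape[0] * shape[1] / 100) or 0
    for _ in range(n_fibers):
        if records and rng.random() < 0.7:
            rec = records[rng.integers(len(records))]
            r = rec.center[0] + rng.normal(0, 2.5 * max(rec.semi_axes))
            c = rec.center[1] + rng.normal(0, 2.5 * max(rec.semi_axes))
        else:
            r = rng.uniform(0, shape[0])
            c = rng.uniform(0, shape[1])
        theta = rng.uniform(0, math.pi)
        length = rng.uniform(30, 120)
        t = np.linspace(-length / 2, length / 2, int(length) * 2)
        rr = np.clip(np.round(r + t * math.sin(theta)).astype(int), 0, shape[0] - 1)
        cc = np.clip(np.round(c + t * math.cos(theta)).astype(int), 0, shape[1] - 1)
        canvas[rr, cc] += rng.uniform(3000, 9000)
    return ndimage.gaussian_filter(canvas, sigma=1.2)


def generate_field(params: StageParams) -> tuple[FieldImage, list[NucleusRecord]]:
    """Render one synthetic multi-channel 16-bit field.

    Returns the field together with the ground-truth nucleus records
    (center, bbox, stage label). Deterministic given ``params.seed``.

    Raises
    ------
    PlacementError
        If non-overlapping placement fails after bounded retries.
    """
    rng = np.random.default_rng(params.seed)
    shape = params.field_shape
    records = _place_nuclei(params, rng)

    nucleus = np.zeros(shape, dtype=np.float64)
    for rec in records:
        _render_nucleus_texture(nucleus, rec, params.grain_px, params.texture_contrast, rng)
    actin = _render_actin(shape, records, params.actin_fiber_density, rng)
    brightfield = 20000.0 + 0.08 * nucleus + 0.15 * actin

    channels = {}
    for name, img in (("nucleus", nucleus), ("actin", actin), ("brightfield", brightfield)):
        noisy = img + rng.normal(0.0, params.noise_sd, size=shape)
        channels[name] = np.clip(noisy, 0, 65535).astype(np.uint16)

    fid = f"stage{params.stage_hours:g}h_seed{params.seed}"
    fimg = FieldImage(
        field_id=fid,
        timepoint_h=params.stage_hours,
        channels=channels,
        bit_depth=16,
    )
    return fimg, records


def generate_stage_dataset(
    stages_h: Sequence[float] = DEFAULT_STAGES_H,
    n_fields_per_stage: int = 4,
    base_params: StageParams | None = None,
    seed: int = 0,
) -> tuple[list[FieldImage], list[tuple[str, NucleusRecord]]]:
    """Fields for every stage, with distinct per-field seeds derived from ``seed``."""
    base = base_params or StageParams()
    fields: list[FieldImage] = []
    truth: list[tuple[str, NucleusRecord]] = []
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(stages_h) * n_fields_per_stage)]
    i = 0
    for stage in stages_h:
        for j in range(n_fields_per_stage):
            p = replace(base, stage_hours=float(stage), seed=child_seeds[i])
            fimg, recs = generate_field(p)
            fimg = FieldImage(
                field_id=f"stage{stage:g}h_f{j}",
                timepoint_h=float(stage),
                channels=fimg.channels,
                bit_depth=16,
            )
            fields.append(fimg)
            truth.extend((fimg.field_id, r) for r in recs)
            i += 1
    return fields, truth


def interior_patch(image: np.ndarray, rec: NucleusRecord, fraction: float = 0.6) -> np.ndarray:
    """Rectangular patch fully inside one nucleus (for texture statistics).

    Centered on the nucleus center with half-side ``fraction *
    semi_minor / sqrt(2)``, which is inscribed in the ellipse for
    fraction <= 1, so border/background pixels never contaminate
    interior texture measurements.
    """
    half = max(2, int(fraction * min(rec.semi_axes) / math.sqrt(2)))
    r = int(round(rec.center[0]))
    c = int(round(rec.center[1]))
    return image[r - half : r + half + 1, c - half : c + half + 1]


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrajectoryParams:
    """Fractional-Brownian trajectory ensemble parameters.

    ``d_eff`` (um^2/s^beta) and ``beta`` parameterize the ensemble law
    ``CD(tau) = d_eff * tau**beta``; defaults match 3-min frame intervals
    over 1 h (21 frames).
    """

    d_eff: float = 0.01
    beta: float = 1.0
    n_frames: int = 21
    frame_interval_s: float = 180.0
    n_trajectories: int = 100
    localization_noise_sd: float = 0.0
    start_spread_um: float = 5.0  # puncta start uniformly in a disk of this radius
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d_eff < 0:
            raise ValueError("d_eff must be >= 0")
        if not 0 < self.beta < 2:
            raise ValueError("beta must lie in the open interval (0, 2)")
        if self.n_frames < 3:
            raise ValueError("need at least 3 frames")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be > 0")
        if self.n_trajectories < 1:
            raise ValueError("n_trajectories must be positive")
        if self.localization_noise_sd < 0:
            raise ValueError("localization_noise_sd must be >= 0")
        if self.start_spread_um < 0:
            raise ValueError("start_spread_um must be >= 0")


@dataclass
class Trajectory:
    """Time-ordered 2D positions (um) of one tracked punctum."""

    trajectory_id: int
    frames: np.ndarray  # int frame indices, strictly increasing
    t_seconds: np.ndarray
    positions: np.ndarray  # (n, 2) -> (x, y) in um
    nucleus_id: int | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.t_seconds = np.asarray(self.t_seconds, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if np.any(np.diff(self.frames) <= 0):
            raise ValueError("frames must be strictly increasing")
        if len(self.frames) != len(self.positions):
            raise ValueError("frames and positions length mismatch")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def frame_interval_s(self) -> float:
        dt = np.diff(self.t_seconds)
        if np.any(np.abs(dt - dt[0]) > 0.01 * dt[0]):
            raise ValueError("frame interval not uniform within 1%")
        return float(dt[0])


def _fbm_position_cov(times: np.ndarray, beta: float, axis_prefactor: float) -> np.ndarray:
    """Covariance of fBm positions: C_ij = p/2 (t_i^b + t_j^b - |t_i - t_j|^b)."""
    ti = times[:, None]
    tj = times[None, :]
    return 0.5 * axis_prefactor * (ti**beta + tj**beta - np.abs(ti - tj) ** beta)


def generate_trajectories(params: TrajectoryParams) -> list[Trajectory]:
    """Sample 2D fBm trajectories obeying ``CD(tau) = d_eff * tau**beta``.

    x and y are independent fractional Brownian motions with Hurst
    exponent ``beta/2``; each axis carries half the prefactor so the 2D
    squared displacement sums to the target law exactly in expectation.
    Synthesis is by Cholesky factorization of the exact position
    covariance, so the law holds at every lag, not asymptotically.
    Starting positions are spread uniformly in a disk of radius
    ``start_spread_um`` (displacements, hence CD, are unaffected).
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_frames
    times = np.arange(n) * params.frame_interval_s
    frames = np.arange(n)

    def _start() -> np.ndarray:
        # puncta are distributed across the nucleus, not co-located:
        # uniform in a disk of radius start_spread_um
        if params.start_spread_um == 0:
            return np.zeros(2)
        r = params.start_spread_um * math.sqrt(rng.uniform())
        th = rng.uniform(0, 2 * math.pi)
        return np.array([r * math.cos(th), r * math.sin(th)])

    L = None
    if params.d_eff > 0.0:
        # per-axis prefactor: E[dx^2] = (d_eff/2) tau^beta
        cov = _fbm_position_cov(times[1:], params.beta, params.d_eff / 2.0)
        # cov is positive definite for t > 0, 0 < beta < 2; tiny jitter for safety
        L = np.linalg.cholesky(cov + 1e-12 * np.eye(n - 1) * cov.diagonal().max())
    trajs = []
    for k in range(params.n_trajectories):
        pos = np.zeros((n, 2))
        if L is not None:
            z = rng.standard_normal((n - 1, 2))
            pos[1:] = L @ z
        pos = pos + _start()
        if params.localization_noise_sd > 0:
            pos = pos + rng.normal(0, params.localization_noise_sd, size=pos.shape)
        trajs.append(Trajectory(k, frames.copy(), times.copy(), pos))
    return trajs


# ---------------------------------------------------------------------------
# Rigid motion
# ---------------------------------------------------------------------------


@dataclass
class RigidMotion:
    """Per-frame rigid transform: rotation about ``center`` plus translation.

    Frame ``t`` maps a point ``p`` to ``R(theta_t) (p - c) + c + d_t``.
    Frame 0 must be the identity.
    """

    angles_rad: np.ndarray
    translations: np.ndarray  # (n_frames, 2)
    center: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.angles_rad = np.asarray(self.angles_rad, dtype=float)
        self.translations = np.asarray(self.translations, dtype=float)
        if self.angles_rad.ndim != 1 or self.translations.shape != (len(self.angles_rad), 2):
            raise ValueError("angles and translations shape mismatch")
        if abs(self.angles_rad[0]) > 1e-12 or np.any(np.abs(self.translations[0]) > 1e-12):
            raise ValueError("frame 0 transform must be the identity")

    @property
    def n_frames(self) -> int:
        return len(self.angles_rad)

    def apply(self, frame: int, points: np.ndarray) -> np.ndarray:
        th = self.angles_rad[frame]
        R = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
        c = np.asarray(self.center)
        return (points - c) @ R.T + c + self.translations[frame]

    def as_global(self) -> tuple[np.ndarray, np.ndarray]:
        """Equivalent (angle, translation) pairs for the about-origin form p -> R p + d."""
        c = np.asarray(self.center)
        ds = np.empty_like(self.translations)
        for t, th in enumerate(self.angles_rad):
            R = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
            ds[t] = c - R @ c + self.translations[t]
        return self.angles_rad.copy(), ds


def apply_rigid_motion(trajs: list[Trajectory], motion: RigidMotion) -> list[Trajectory]:
    """Corrupt trajectories by a shared per-frame rigid nuclear motion."""
    out = []
    for tr in trajs:
        if tr.n_frames != motion.n_frames:
            raise ValueError(
                f"trajectory {tr.trajectory_id} has {tr.n_frames} frames, "
                f"motion has {motion.n_frames}"
            )
        pos = np.empty_like(tr.positions)
        for i, f in enumerate(tr.frames):
            pos[i] = motion.apply(int(f), tr.positions[i])
        out.append(Trajectory(tr.trajectory_id, tr.frames.copy(), tr.t_seconds.copy(), pos, tr.nucleus_id))
    return out


# ---------------------------------------------------------------------------
# Puncta movie rendering
# ---------------------------------------------------------------------------


def render_puncta_movie(
    trajs: list[Trajectory],
    shape: tuple[int, int] = (128, 128),
    psf_sigma_px: float = 1.5,
    noise_sd: float = 0.0,
    amplitude: float = 1000.0,
    background: float = 100.0,
    pixel_size_um: float = 1.0,
    poisson: bool = False,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Render trajectories as Gaussian spots per frame.

    Positions are interpreted in um and divided by ``pixel_size_um`` to
    obtain (x, y) pixel coordinates (x -> column, y -> row). Returns the
    (n_frames, H, W) float stack and the ground-truth (n_frames,
    n_puncta, 2) pixel coordinates.

    Raises
    ------
    ValueError
        If any spot center falls outside the frame, listing offenders.
    """
    rng = np.random.default_rng(seed)
    n_frames = trajs[0].n_frames
    coords = np.stack([tr.positions / pixel_size_um for tr in trajs], axis=1)  # (T, P, 2)
    offenders = []
    for t in range(n_frames):
        for p in range(coords.shape[1]):
            x, y = coords[t, p]
            if not (0 <= x < shape[1] and 0 <= y < shape[0]):
                offenders.append((t, p, float(x), float(y)))
    if offenders:
        raise ValueError(f"spots out of frame: {offenders[:10]}" + (" ..." if len(offenders) > 10 else ""))

    rr = np.arange(shape[0])[:, None]
    cc = np.arange(shape[1])[None, :]
    stack = np.full((n_frames,) + shape, background, dtype=np.float64)
    for t in range(n_frames):
        for p in range(coords.shape[1]):
            x, y = coords[t, p]
            g = np.exp(-((rr - y) ** 2 + (cc - x) ** 2) / (2 * psf_sigma_px**2))
            stack[t] += amplitude * g
    if poisson:
        stack = rng.poisson(np.clip(stack, 0, None)).astype(np.float64)
    if noise_sd > 0:
        stack += rng.normal(0, noise_sd, size=stack.shape)
    return stack, coords
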