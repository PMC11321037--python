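"""Chromatin-mobility analysis from tracked puncta.

Pipeline: estimate and remove rigid whole-nucleus motion (rotation +
translation per frame), detect and link fluorescent puncta, compute the
chromatin displacement ``CD(tau) = <(X_{t+tau}-X_t)^2 + (Y_{t+tau}-Y_t)^2>``
(a 2D MSD, time-averaged over start times t), and fit the power law
``CD = D_eff * tau**beta`` by ordinary least squares in log-log space.
``D_eff`` is read as chromatin fluidity and ``beta`` as the anomalous
exponent (beta = 1 Brownian, beta < 1 subdiffusive).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats
from skimage.feature import peak_local_max

from .synthetic import RigidMotion, Trajectory


@dataclass
class CDCurve:
    """Chromatin displacement vs lag time."""

    lags_tau_s: np.ndarray
    cd_um2: np.ndarray
    n_pairs: np.ndarray
    source: str = "single"  # "single" (time-average) or "ensemble"

    def __post_init__(self) -> None:
        self.lags_tau_s = np.asarray(self.lags_tau_s, dtype=float)
        self.cd_um2 = np.asarray(self.cd_um2, dtype=float)
        self.n_pairs = np.asarray(self.n_pairs, dtype=int)
        if np.any(self.cd_um2 < 0):
            raise ValueError("cd must be non-negative")


@dataclass
class PowerLawFit:
    """Fitted CD(tau) = d_eff * tau**beta with log-log goodness of fit."""

    d_eff: float
    beta: float
    r_squared: float
    lag_range_s: tuple[float, float]
    n_lags: int
    n_zero_excluded: int = 0

    def predict(self, tau: np.ndarray) -> np.ndarray:
        return self.d_eff * np.asarray(tau, dtype=float) ** self.beta


# ---------------------------------------------------------------------------
# Registration
# ---------------------------------------------------------------------------


def _kabsch_2d(A: np.ndarray, B: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid transform mapping A onto B (rotation only, no reflection)."""
    ca = A.mean(axis=0)
    cb = B.mean(axis=0)
    H = (A - ca).T @ (B - cb)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, d]) @ U.T
    t = cb - R @ ca
    return R, t


def register_frames(
    point_sets: np.ndarray | list[np.ndarray],
) -> tuple[RigidMotion, np.ndarray]:
    """Estimate and remove per-frame rigid nuclear motion from matched puncta.

    ``point_sets`` holds the same >= 3 puncta in every frame, shape
    (n_frames, n_points, 2). Each frame is aligned to frame 0 by
    closed-form orthogonal Procrustes (reflections rejected); the inverse
    transform is applied to all points. Returns the estimated motion (in
    the about-origin form ``p -> R p + d``) and the corrected point sets.
    """
    pts = np.asarray(point_sets, dtype=float)
    if pts.ndim != 3 or pts.shape[2] != 2:
        raise ValueError("expected point sets of shape (n_frames, n_points, 2)")
    if pts.shape[1] < 3:
        raise ValueError("need at least 3 matched puncta per frame")
    n_frames = pts.shape[0]
    angles = np.zeros(n_frames)
    trans = np.zeros((n_frames, 2))
    corrected = np.empty_like(pts)
    corrected[0] = pts[0]
    for t in range(1, n_frames):
        R, d = _kabsch_2d(pts[0], pts[t])
        angles[t] = math.atan2(R[1, 0], R[0, 0])
        trans[t] = d
        corrected[t] = (pts[t] - d) @ R  # R^T applied from the right
    motion = RigidMotion(angles_rad=angles, translations=trans, center=(0.0, 0.0))
    return motion, corrected


def register_masks(masks: np.ndarray) -> RigidMotion:
    """Rigid motion estimate from per-frame nucleus masks.

    Translation from the centroid drift, rotation from the principal-axis
    orientation of the mask's second moments (valid for elongated
    nuclei; orientation is tracked continuously to avoid 180-degree
    flips).
    """
    masks = np.asarray(masks, dtype=bool)
    n_frames = masks.shape[0]
    angles = np.zeros(n_frames)
    trans = np.zeros((n_frames, 2))
    cents = np.array([ndimage.center_of_mass(m) for m in masks])  # (row, col)

    def _orientation(m):
        rr, cc = np.nonzero(m)
        r0, c0 = rr.mean(), cc.mean()
        mu20 = np.mean((cc - c0) ** 2)
        mu02 = np.mean((rr - r0) ** 2)
        mu11 = np.mean((cc - c0) * (rr - r0))
        return 0.5 * math.atan2(2 * mu11, mu20 - mu02)

    th0 = _orientation(masks[0])
    prev = 0.0
    for t in range(n_frames):
        raw = _orientation(masks[t]) - th0
        # unwrap: mask orientation is defined mod pi
        while raw - prev > math.pi / 2:
            raw -= math.pi
        while raw - prev < -math.pi / 2:
            raw += math.pi
        angles[t] = raw
        prev = raw
        # (x, y) convention: x = col, y = row
        trans[t] = (cents[t, 1] - cents[0, 1], cents[t, 0] - cents[0, 0])
    angles[0] = 0.0
    trans[0] = 0.0
    return RigidMotion(angles_rad=angles, translations=trans, center=(0.0, 0.0))


def remove_motion(trajs: list[Trajectory], motion: RigidMotion) -> list[Trajectory]:
    """Apply the inverse of an estimated rigid motion to trajectories."""
    angles, ds = motion.as_global()
    out = []
    for tr in trajs:
        pos = np.empty_like(tr.positions)
        for i, f in enumerate(tr.frames):
            th = angles[int(f)]
            R = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
            pos[i] = R.T @ (tr.positions[i] - ds[int(f)])
        out.append(Trajectory(tr.trajectory_id, tr.frames.copy(), tr.t_seconds.copy(), pos, tr.nucleus_id))
    return out


# ---------------------------------------------------------------------------
# Detection and linking
# ---------------------------------------------------------------------------


def detect_puncta(
    frame: np.ndarray,
    expected_sigma_px: float,
    mask: np.ndarray | None = None,
    score_cutoff: float = 0.2,
) -> tuple[np.ndarray, np.ndarray]:
    """Laplacian-of-Gaussian blob detection with [0, 1] scores.

    Returns (coords, scores): coords are (n, 2) in (x, y) pixel order;
    scores are the per-spot LoG response normalized by the frame maximum
    (the "possibility" surrogate). Detections outside ``mask`` are
    discarded. An empty result is not an error.
    """
    frame = np.asarray(frame, dtype=np.float64)
    resp = -ndimage.gaussian_laplace(frame, sigma=expected_sigma_px)
    resp = np.clip(resp, 0, None)
    if resp.max() <= 0:
        return np.empty((0, 2)), np.empty(0)
    peaks = peak_local_max(
        resp, min_distance=max(1, int(round(2 * expected_sigma_px))),
        threshold_abs=score_cutoff * resp.max(),
    )
    scores = resp[peaks[:, 0], peaks[:, 1]] / resp.max()
    coords = peaks[:, ::-1].astype(float)  # (row, col) -> (x, y)
    if mask is not None:
        keep = mask[peaks[:, 0], peaks[:, 1]]
        coords, scores = coords[keep], scores[keep]
    order = np.argsort(-scores)
    return coords[order], scores[order]


def link_tracks(
    detections_per_frame: list[np.ndarray],
    max_disp_px: float,
    max_gap_frames: int = 0,
    min_length: int = 3,
    frame_interval_s: float = 180.0,
    pixel_size_um: float = 1.0,
) -> list[Trajectory]:
    """Greedy nearest-neighbor linking of per-frame detections.

    Links the closest (track, detection) pairs within ``max_disp_px``,
    bridges gaps up to ``max_gap_frames``, and drops tracks shorter than
    ``min_length``. Positions are converted to um via ``pixel_size_um``.
    """
    active: list[dict] = []
    done: list[dict] = []
    next_id = 0
    for f, dets in enumerate(detections_per_frame):
        dets = np.asarray(dets, dtype=float).reshape(-1, 2)
        unmatched = set(range(len(dets)))
        if active and len(dets):
            cand = []
            for ti, tr in enumerate(active):
                gap = f - tr["frames"][-1]
                if gap > max_gap_frames + 1:
                    continue
                d = np.linalg.norm(dets - tr["pos"][-1], axis=1)
                for di in range(len(dets)):
                    if d[di] <= max_disp_px * gap:
                        cand.append((d[di], ti, di))
            cand.sort()
            used_t: set[int] = set()
            for dist, ti, di in cand:
                if ti in used_t or di not in unmatched:
                    continue
                active[ti]["frames"].append(f)
                active[ti]["pos"].append(dets[di])
                used_t.add(ti)
                unmatched.discard(di)
        still = []
        for tr in active:
            if f - tr["frames"][-1] > max_gap_frames:
                done.append(tr)
            else:
                still.append(tr)
        active = still
        for di in sorted(unmatched):
            active.append({"id": next_id, "frames": [f], "pos": [dets[di]]})
            next_id += 1
    done.extend(active)
    out = []
    for tr in done:
        if len(tr["frames"]) < min_length:
            continue
        frames = np.asarray(tr["frames"])
        out.append(
            Trajectory(
                trajectory_id=tr["id"],
                frames=frames,
                t_seconds=frames * frame_interval_s,
                positions=np.asarray(tr["pos"]) * pixel_size_um,
            )
        )
    return out


# ---------------------------------------------------------------------------
# CD and power-law fitting
# ---------------------------------------------------------------------------


def compute_cd(traj: Trajectory, max_lag_fraction: float = 0.5) -> CDCurve:
    """Time-averaged squared displacement per lag for one trajectory.

    For lag ``tau = k * dt`` the average runs over all start times t; lags
    are limited to ``max_lag_fraction`` of the track duration. Units um^2.
    """
    if traj.n_frames < 3:
        raise ValueError("trajectory must have at least 3 frames")
    dt = traj.frame_interval_s
    n = traj.n_frames
    max_k = max(1, int((n - 1) * max_lag_fraction))
    lags, cds, npairs = [], [], []
    for k in range(1, max_k + 1):
        d = traj.positions[k:] - traj.positions[:-k]
        sq = (d**2).sum(axis=1)
        lags.append(k * dt)
        cds.append(float(sq.mean()))
        npairs.append(len(sq))
    return CDCurve(np.array(lags), np.array(cds), np.array(npairs), source="single")


def ensemble_cd(curves: list[CDCurve]) -> CDCurve:
    """n_pairs-weighted mean CD over curves sharing one lag grid."""
    if not curves:
        raise ValueError("no curves")
    lags = curves[0].lags_tau_s
    for c in curves[1:]:
        if len(c.lags_tau_s) != len(lags) or np.any(np.abs(c.lags_tau_s - lags) > 1e-9):
            raise ValueError("mismatched lag grids")
    w = np.stack([c.n_pairs for c in curves]).astype(float)
    v = np.stack([c.cd_um2 for c in curves])
    tot = w.sum(axis=0)
    return CDCurve(lags.copy(), (w * v).sum(axis=0) / tot, tot.astype(int), source="ensemble")


def fit_power_law(
    curve: CDCurve, lag_range: tuple[float, float] | None = None
) -> PowerLawFit:
    """OLS of log(cd) on log(tau): beta = slope, d_eff = exp(intercept).

    Zero-cd lags are excluded (their count is reported); at least 3 usable
    lags are required.
    """
    lags = curve.lags_tau_s
    cds = curve.cd_um2
    if lag_range is not None:
        sel = (lags >= lag_range[0]) & (lags <= lag_range[1])
        lags, cds = lags[sel], cds[sel]
    pos = cds > 0
    n_zero = int((~pos).sum())
    lags, cds = lags[pos], cds[pos]
    if len(lags) < 3:
        raise ValueError("fewer than 3 usable (positive) lags in range")
    res = stats.linregress(np.log(lags), np.log(cds))
    return PowerLawFit(
        d_eff=float(np.exp(res.intercept)),
        beta=float(res.slope),
        r_squared=float(res.rvalue**2),
        lag_range_s=(float(lags[0]), float(lags[-1])),
        n_lags=len(lags),
        n_zero_excluded=n_zero,
    )


def fit_power_law_nls(curve: CDCurve, lag_range: tuple[float, float] | None = None) -> PowerLawFit:
    """Nonlinear least squares on the raw scale — cross-check estimator."""
    from scipy.optimize import curve_fit

    lags = curve.lags_tau_s
    cds = curve.cd_um2
    if lag_range is not None:
        sel = (lags >= lag_range[0]) & (lags <= lag_range[1])
        lags, cds = lags[sel], cds[sel]
    pos = cds > 0
    lags, cds = lags[pos], cds[pos]
    if len(lags) < 3:
        raise ValueError("fewer than 3 usable lags")
    start = fit_power_law(CDCurve(lags, cds, np.ones(len(lags), dtype=int)))
    popt, _ = curve_fit(
        lambda t, d, b: d * t**b, lags, cds, p0=[start.d_eff, start.beta], maxfev=10000
    )
    resid = cds - popt[0] * lags ** popt[1]
    ss_res = float((resid**2).sum())
    ss_tot = float(((cds - cds.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return PowerLawFit(float(popt[0]), float(popt[1]), r2, (float(lags[0]), float(lags[-1])), len(lags))


def analyze_trajectories(
    trajs: list[Trajectory], max_lag_fraction: float = 0.5,
    lag_range: tuple[float, float] | None = None,
) -> tuple[CDCurve, PowerLawFit, list[PowerLawFit]]:
    """Per-trajectory time-averaged CD, ensemble mean, and power-law fits.

    Returns (ensemble curve, ensemble fit, per-trajectory fits). Tracks
    too short to fit are skipped in the per-trajectory list.
    """
    curves = [compute_cd(t, max_lag_fraction) for t in trajs]
    ens = ensemble_cd(curves)
    ens_fit = fit_power_law(ens, lag_range)
    per = []
    for c in curves:
        try:
            per.append(fit_power_law(c, lag_range))
        except ValueError:
            continue
    return ens, ens_fit, per


def compare_conditions(
    fits_a: list[PowerLawFit], fits_b: list[PowerLawFit], alpha: float = 0.05
) -> dict:
    """Two-sided rank-sum comparison of d_eff and beta between conditions.

    Mirrors per-condition parameter comparisons between control and
    treated nuclei. Identical samples report p = 1 with a degenerate
    flag. Effect direction is the sign of median(b) - median(a).
    """
    if len(fits_a) < 3 or len(fits_b) < 3:
        raise ValueError("need at least 3 nuclei per condition")
    out: dict = {"alpha": alpha, "n_a": len(fits_a), "n_b": len(fits_b)}
    for param in ("d_eff", "beta"):
        a = np.array([getattr(f, param) for f in fits_a])
        b = np.array([getattr(f, param) for f in fits_b])
        degenerate = np.array_equal(np.sort(a), np.sort(b))
        if degenerate:
            p = 1.0
            stat = float("nan")
        else:
            stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        out[param] = {
            "statistic": float(stat),
            "p_value": float(p),
            "significant": bool(p < alpha),
            "direction": int(np.sign(np.median(b) - np.median(a))),
            "median_a": float(np.median(a)),
            "median_b": float(np.median(b)),
            "degenerate": degenerate,
        }
    return out


def plot_cd_loglog(curves: dict[str, CDCurve], fits: dict[str, PowerLawFit] | None, path: str) -> None:
    """Log-log CD vs lag plot for one or more conditions, written to file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for name, c in curves.items():
        ax.loglog(c.lags_tau_s, c.cd_um2, "o", label=name, ms=4)
        if fits and name in fits:
            f = fits[name]
            tt = np.linspace(c.lags_tau_s[0], c.lags_tau_s[-1], 50)
            ax.loglog(tt, f.predict(tt), "-", lw=1,
                      label=f"{name} fit: $D_{{eff}}$={f.d_eff:.3g}, $\\beta$={f.beta:.2f}")
    ax.set_xlabel(r"lag $\tau$ (s)")
    ax.set_ylabel(r"CD ($\mu m^2$)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
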