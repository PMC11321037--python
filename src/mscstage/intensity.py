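"""Mean fluorescent intensity (MFI) quantitation and group comparisons.

MFI is the arithmetic mean of raw (16-bit) pixel values inside a nuclear
ROI, optionally rescaled to a reference exposure time when timepoints
were acquired at different exposures. Groups of measurements across
differentiation timepoints are compared by a Kruskal-Wallis or one-way
ANOVA omnibus test followed by post-hoc pairwise comparisons with
multiplicity control (Dunn/Holm after Kruskal-Wallis, Tukey HSD after
ANOVA), with significance star-coding ns/*/**/***/**** at
0.05/0.01/0.001/0.0001 (strict inequalities).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class ROIMeasurement:
    field_id: str
    roi_id: int
    timepoint_h: float
    mfi: float
    area_px: int
    marker: str = ""


def star_code(p: float) -> str:
    """Map a p-value to significance stars (strict thresholds)."""
    if p < 0.0001:
        return "****"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def measure_mfi(
    channel: np.ndarray,
    roi_mask: np.ndarray,
    field_id: str = "",
    roi_id: int = 0,
    timepoint_h: float = 0.0,
    marker: str = "",
    exposure_s: float | None = None,
    reference_exposure_s: float | None = None,
) -> ROIMeasurement:
    """Mean raw pixel value within one ROI.

    If both exposures are given, the MFI is normalized to the reference
    exposure (``mfi * reference / actual``), making timepoints acquired
    at different exposure times comparable.
    """
    channel = np.asarray(channel)
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if channel.shape != roi_mask.shape:
        raise ValueError("image and mask shapes differ")
    area = int(roi_mask.sum())
    if area == 0:
        raise ValueError("empty ROI mask")
    mfi = float(channel[roi_mask].mean())
    if exposure_s is not None and reference_exposure_s is not None:
        mfi *= reference_exposure_s / exposure_s
    return ROIMeasurement(field_id, roi_id, timepoint_h, mfi, area, marker)


def measure_field_mfi(
    fimg,
    marker_channel: str,
    reference_exposure_s: float | None = None,
    min_size: int = 50,
    max_size: int = 100,
) -> list[ROIMeasurement]:
    """MFI of every segmented nucleus in one field.

    ROIs come from Otsu segmentation of the field's nucleus channel
    (size-filtered like the staging pipeline); the marker channel is
    measured raw. Exposure normalization applies when the field carries
    an exposure time and a reference is given.
    """
    from skimage import measure as skmeasure

    from .segment import otsu_threshold, size_filter, to_uint8_minmax

    nuc8 = to_uint8_minmax(fimg.channels["nucleus"])
    labeled = skmeasure.label(nuc8 > otsu_threshold(nuc8), connectivity=2)
    from .segment import segment_nuclei

    regions = size_filter(segment_nuclei(nuc8), min_size, max_size)
    out = []
    for r in regions:
        out.append(
            measure_mfi(
                fimg.channels[marker_channel],
                labeled == r.label,
                field_id=fimg.field_id,
                roi_id=r.label,
                timepoint_h=fimg.timepoint_h,
                marker=marker_channel,
                exposure_s=fimg.exposure_s,
                reference_exposure_s=reference_exposure_s,
            )
        )
    return out


def _dunn_posthoc(groups: dict, alpha: float) -> list[dict]:
    """Dunn's z-tests on pooled ranks with tie correction, Holm-adjusted."""
    names = sorted(groups)
    all_vals = np.concatenate([groups[g] for g in names])
    n_total = len(all_vals)
    ranks = stats.rankdata(all_vals)
    mean_ranks = {}
    start = 0
    for g in names:
        k = len(groups[g])
        mean_ranks[g] = ranks[start : start + k].mean()
        start += k
    _, tie_counts = np.unique(all_vals, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term
    rows = []
    pvals = []
    for a, b in combinations(names, 2):
        se = np.sqrt(base_var * (1.0 / len(groups[a]) + 1.0 / len(groups[b])))
        if se == 0:
            p = 1.0
            z = 0.0
        else:
            z = (mean_ranks[a] - mean_ranks[b]) / se
            p = 2.0 * stats.norm.sf(abs(z))
        rows.append({"group_a": a, "group_b": b, "statistic": float(z), "p_raw": float(p)})
        pvals.append(p)
    adj = multipletests(pvals, alpha=alpha, method="holm")[1]
    for row, pa in zip(rows, adj):
        row["p_adjusted"] = float(pa)
        row["stars"] = star_code(pa)
    return rows


def _tukey_posthoc(groups: dict, alpha: float) -> list[dict]:
    names = sorted(groups)
    res = stats.tukey_hsd(*[groups[g] for g in names])
    rows = []
    for i, j in combinations(range(len(names)), 2):
        p = float(res.pvalue[i, j])
        rows.append(
            {
                "group_a": names[i],
                "group_b": names[j],
                "statistic": float(res.statistic[i, j]),
                "p_adjusted": p,
                "stars": star_code(p),
            }
        )
    return rows


def group_compare(
    measurements,
    marker: str | None = None,
    test: str = "kruskal_wallis",
    alpha: float = 0.05,
) -> dict:
    """Omnibus + post-hoc comparison of MFI across timepoint groups.

    ``measurements`` is a list of :class:`ROIMeasurement` or a DataFrame
    with columns ``timepoint_h`` and ``mfi`` (and optionally ``marker``).
    Requires >= 2 groups with >= 3 measurements each.
    """
    if test not in ("kruskal_wallis", "anova"):
        raise ValueError("test must be 'kruskal_wallis' or 'anova'")
    if isinstance(measurements, pd.DataFrame):
        df = measurements
    else:
        df = pd.DataFrame(
            {
                "timepoint_h": [m.timepoint_h for m in measurements],
                "mfi": [m.mfi for m in measurements],
                "marker": [m.marker for m in measurements],
            }
        )
    if marker is not None and "marker" in df.columns:
        df = df[df["marker"] == marker]
    groups = {float(tp): g["mfi"].to_numpy(dtype=float) for tp, g in df.groupby("timepoint_h")}
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for tp, vals in groups.items():
        if len(vals) < 3:
            raise ValueError(f"group {tp} h has fewer than 3 measurements")

    identical = all(
        np.array_equal(np.sort(v), np.sort(next(iter(groups.values())))) for v in groups.values()
    )
    if test == "kruskal_wallis":
        if identical:
            stat, p = 0.0, 1.0
        else:
            stat, p = stats.kruskal(*groups.values())
        posthoc = _dunn_posthoc(groups, alpha)
    else:
        if identical:
            stat, p = 0.0, 1.0
        else:
            stat, p = stats.f_oneway(*groups.values())
        posthoc = _tukey_posthoc(groups, alpha)
    return {
        "test": test,
        "marker": marker,
        "omnibus_statistic": float(stat),
        "omnibus_p": float(p),
        "omnibus_stars": star_code(float(p)),
        "significant": bool(p < alpha),
        "alpha": alpha,
        "group_sizes": {str(k): int(len(v)) for k, v in groups.items()},
        "group_means": {str(k): float(np.mean(v)) for k, v in groups.items()},
        "posthoc": posthoc,
        "degenerate": identical,
    }
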