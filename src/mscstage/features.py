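"""Classic texture features for the non-deep-learning baselines.

The 13 Haralick statistics are computed from symmetric, normalized
gray-level co-occurrence matrices at distance 1 for the four right-angle
offsets (0, 45, 90, 135 degrees) and averaged over offsets, which makes
the feature vector invariant to 90-degree rotations of the image.
"""

from __future__ import annotations

import numpy as np
from skimage.feature import graycomatrix

from .segment import NucleusCrop, otsu_threshold

HARALICK_NAMES = (
    "angular_second_moment",
    "contrast",
    "correlation",
    "sum_of_squares_variance",
    "inverse_difference_moment",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "entropy",
    "difference_variance",
    "difference_entropy",
    "info_measure_corr_1",
    "info_measure_corr_2",
)

_ANGLES = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)


def glcm_matrices(image: np.ndarray, levels: int = 256) -> np.ndarray:
    """Symmetric normalized GLCMs at distance 1, shape (levels, levels, 4)."""
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("expected a single-channel 2D image")
    g = graycomatrix(
        image.astype(np.uint8), distances=[1], angles=list(_ANGLES), levels=levels,
        symmetric=True, normed=True,
    )
    return g[:, :, 0, :]


def haralick_from_glcm(p: np.ndarray) -> np.ndarray:
    """The 13 Haralick statistics of one normalized GLCM.

    A single-entry GLCM (constant image) yields defined degenerate
    values: contrast 0, ASM 1, correlation 1, entropies 0.
    """
    levels = p.shape[0]
    i = np.arange(levels, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)

    # p_{x+y}(k), k = 0..2(levels-1); p_{x-y}(k), k = 0..levels-1
    k_sum = (ii + jj).astype(int)
    k_diff = np.abs(ii - jj).astype(int)
    p_sum = np.bincount(k_sum.ravel(), weights=p.ravel(), minlength=2 * levels - 1)
    p_diff = np.bincount(k_diff.ravel(), weights=p.ravel(), minlength=levels)

    def _ent(q: np.ndarray) -> float:
        nz = q[q > 0]
        return float(-(nz * np.log(nz)).sum())

    asm = float((p**2).sum())
    contrast = float(((ii - jj) ** 2 * p).sum())
    mu_x = float((i * px).sum())
    mu_y = float((i * py).sum())
    var_x = float(((i - mu_x) ** 2 * px).sum())
    var_y = float(((i - mu_y) ** 2 * py).sum())
    if var_x > 0 and var_y > 0:
        correlation = float(((ii - mu_x) * (jj - mu_y) * p).sum() / np.sqrt(var_x * var_y))
    else:
        correlation = 1.0
    sum_sq_var = float(((ii - mu_x) ** 2 * p).sum())
    idm = float((p / (1.0 + (ii - jj) ** 2)).sum())
    ks = np.arange(len(p_sum), dtype=np.float64)
    sum_avg = float((ks * p_sum).sum())
    sum_ent = _ent(p_sum)
    sum_var = float(((ks - sum_avg) ** 2 * p_sum).sum())
    entropy = _ent(p)
    kd = np.arange(len(p_diff), dtype=np.float64)
    diff_avg = float((kd * p_diff).sum())
    diff_var = float(((kd - diff_avg) ** 2 * p_diff).sum())
    diff_ent = _ent(p_diff)

    hx = _ent(px)
    hy = _ent(py)
    pxy_outer = np.outer(px, py)
    mask = (p > 0) & (pxy_outer > 0)
    hxy1 = float(-(p[mask] * np.log(pxy_outer[mask])).sum())
    m2 = pxy_outer > 0
    hxy2 = float(-(pxy_outer[m2] * np.log(pxy_outer[m2])).sum())
    denom = max(hx, hy)
    imc1 = (entropy - hxy1) / denom if denom > 0 else 0.0
    arg = max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - entropy)))
    imc2 = float(np.sqrt(arg))

    return np.array([
        asm, contrast, correlation, sum_sq_var, idm, sum_avg, sum_var,
        sum_ent, entropy, diff_var, diff_ent, imc1, imc2,
    ])


def haralick_features(image: np.ndarray, levels: int = 256) -> np.ndarray:
    """Offset-averaged 13-vector of Haralick statistics for one 8-bit crop."""
    mats = glcm_matrices(image, levels=levels)
    return np.mean([haralick_from_glcm(mats[:, :, a]) for a in range(mats.shape[2])], axis=0)


def nuclear_area(image_or_mask: np.ndarray) -> int:
    """Foreground pixel count; raw crops are re-thresholded via Otsu.

    Raises
    ------
    ValueError
        If the foreground is empty.
    """
    arr = np.asarray(image_or_mask)
    if arr.dtype == bool:
        mask = arr
    else:
        mask = arr > otsu_threshold(arr)
    area = int(mask.sum())
    if area == 0:
        raise ValueError("empty foreground: no nucleus in crop")
    return area


def texture_feature_table(crops, channel: str = "nucleus", levels: int = 256):
    """(n_crops, 14) array: 13 Haralick statistics + nuclear area, plus names."""
    rows = []
    for c in crops:
        img = c.channels[channel]
        feats = haralick_features(img, levels=levels)
        try:
            area = nuclear_area(img)
        except ValueError:
            area = 0
        rows.append(np.concatenate([feats, [area]]))
    return np.asarray(rows), list(HARALICK_NAMES) + ["area_px"]
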