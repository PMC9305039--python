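"""Brightfield immunohistochemistry quantification.

Pixels are moved to optical-density (OD) space, ``OD = -ln(I / I0)``, where
dye concentrations mix linearly (Beer--Lambert); stain separation is then a
per-pixel linear solve against a stain matrix whose rows are unit dye
absorption vectors. Downstream quantities: thresholded area fractions,
scale-normalised Laplacian-of-Gaussian blob detection (scikit-image),
nearest-blob distances, greedy top-k region counts, and nucleus-anchored
positivity cross-tables tested with Fisher's exact test.

Conventions: coordinates are (row, col), 0-based, origin top-left; distances
in pixels; background intensity I0 = 255 by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from skimage.feature import blob_log

from .core_stats import ContingencyTable2x2, fisher_exact_2x2

logger = logging.getLogger(__name__)

__all__ = [
    "StainMatrix",
    "BlobSet",
    "ColocalizationResult",
    "HEMATOXYLIN",
    "DAB",
    "default_hdab_purple",
    "white_balance",
    "rgb_to_od",
    "od_to_rgb",
    "separate_stains",
    "mix_stains",
    "quantify_area",
    "detect_blobs",
    "nearest_blob_distances",
    "colocalization_table",
    "count_top_regions",
]

# Published H-DAB absorption vectors (Ruifrok & Johnston), unit-normalised.
HEMATOXYLIN = np.array([0.650, 0.704, 0.286])
DAB = np.array([0.269, 0.568, 0.778])


@dataclass(frozen=True)
class StainMatrix:
    """Rows = unit dye absorption vectors in OD-RGB space."""

    vectors: np.ndarray  # (3, 3)
    names: tuple[str, str, str] = ("hematoxylin", "dab", "purple")

    def __post_init__(self) -> None:
        v = np.asarray(self.vectors, dtype=float)
        if v.shape != (3, 3):
            raise ValueError(f"stain matrix must be 3x3, got {v.shape}")
        if np.any(v < 0):
            raise ValueError("stain vectors must be non-negative")
        norms = np.linalg.norm(v, axis=1)
        if np.any(norms == 0):
            raise ValueError("zero stain vector")
        v = v / norms[:, None]
        if np.linalg.cond(v) >= 1e6:
            raise ValueError("stain matrix is singular or near-singular")
        object.__setattr__(self, "vectors", v)

    @property
    def inverse(self) -> np.ndarray:
        return np.linalg.inv(self.vectors)


# A blob set is an (n, 3) float array of (row, col, sigma) detections.
BlobSet = np.ndarray


@dataclass(frozen=True)
class ColocalizationResult:
    table: ContingencyTable2x2
    odds_ratio: float
    p_value: float
    radius: float


def default_hdab_purple() -> StainMatrix:
    """H-DAB plus a residual third channel for the purple chromogen.

    The third vector is the orthogonal complement of the hematoxylin and DAB
    vectors with negative components clipped to zero and the result
    re-normalised, keeping the matrix invertible and non-negative.
    """
    residual = np.cross(HEMATOXYLIN, DAB)
    residual = np.clip(residual, 0.0, None)
    return StainMatrix(np.vstack([HEMATOXYLIN, DAB, residual]))


def _check_rgb(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) RGB image, got shape {img.shape}")
    return img


def white_balance(img: np.ndarray, percentile: float = 99.9) -> np.ndarray:
    """Rescale each channel so its given percentile maps to 255."""
    img = _check_rgb(img).astype(float)
    ref = np.percentile(img.reshape(-1, 3), percentile, axis=0)
    ref = np.where(ref <= 0, 1.0, ref)
    return np.clip(img / ref[None, None, :] * 255.0, 0, 255).astype(np.uint8)


def rgb_to_od(img: np.ndarray, i0: float = 255.0) -> np.ndarray:
    """Optical density per channel: ``-ln(max(I, 1) / I0)``."""
    img = _check_rgb(img).astype(float)
    return -np.log(np.maximum(img, 1.0) / i0)


def od_to_rgb(od: np.ndarray, i0: float = 255.0) -> np.ndarray:
    """Inverse Beer--Lambert: 8-bit intensities ``I0 * exp(-OD)``."""
    od = np.asarray(od, dtype=float)
    return np.clip(np.rint(i0 * np.exp(-od)), 0, 255).astype(np.uint8)


def separate_stains(od: np.ndarray, m: StainMatrix) -> np.ndarray:
    """Per-pixel dye concentrations from an OD image.

    Solves ``OD = c @ M`` by the matrix inverse; negative concentrations are
    clipped to zero after solving.
    """
    od = np.asarray(od, dtype=float)
    if od.ndim != 3 or od.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) OD image, got shape {od.shape}")
    conc = od @ m.inverse
    return np.clip(conc, 0.0, None)


def mix_stains(conc: np.ndarray, m: StainMatrix) -> np.ndarray:
    """Re-mix per-stain concentrations into an OD image."""
    return np.asarray(conc, dtype=float) @ m.vectors


def quantify_area(channel: np.ndarray, threshold: float) -> float:
    """Fraction of pixels strictly above ``threshold``."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    channel = np.asarray(channel, dtype=float)
    return float(np.count_nonzero(channel > threshold)) / channel.size


def detect_blobs(
    channel: np.ndarray,
    min_sigma: float = 2.0,
    max_sigma: float = 6.0,
    num_sigma: int = 9,
    threshold: float = 0.1,
) -> BlobSet:
    """Scale-normalised Laplacian-of-Gaussian blob detection.

    Thin wrapper over :func:`skimage.feature.blob_log`; returns an (n, 3)
    array of (row, col, sigma).
    """
    if not 0 < min_sigma <= max_sigma:
        raise ValueError("need max_sigma >= min_sigma > 0")
    blobs = blob_log(
        np.asarray(channel, dtype=float),
        min_sigma=min_sigma,
        max_sigma=max_sigma,
        num_sigma=num_sigma,
        threshold=threshold,
    )
    return blobs.reshape(-1, 3)


def nearest_blob_distances(a: BlobSet, b: BlobSet) -> np.ndarray:
    """Per blob of ``a``, Euclidean distance to the nearest blob of ``b``."""
    a = np.asarray(a, dtype=float).reshape(-1, 3)
    b = np.asarray(b, dtype=float).reshape(-1, 3)
    if b.shape[0] == 0:
        raise ValueError("reference blob set is empty; distances undefined")
    if a.shape[0] == 0:
        return np.empty(0)
    dists, _ = cKDTree(b[:, :2]).query(a[:, :2])
    return np.asarray(dists, dtype=float)


def colocalization_table(
    nuclei: BlobSet, stain_b: BlobSet, stain_c: BlobSet, radius: float
) -> ColocalizationResult:
    """Nucleus-anchored positivity cross-table with Fisher's exact test.

    A nucleus is positive for a stain iff that stain has a blob within
    ``radius`` pixels of the nucleus centre.
    """
    nuclei = np.asarray(nuclei, dtype=float).reshape(-1, 3)
    if nuclei.shape[0] == 0:
        raise ValueError("empty nucleus set")
    if radius <= 0:
        raise ValueError("radius must be positive")

    def positive(stain: BlobSet) -> np.ndarray:
        stain = np.asarray(stain, dtype=float).reshape(-1, 3)
        if stain.shape[0] == 0:
            return np.zeros(nuclei.shape[0], dtype=bool)
        d, _ = cKDTree(stain[:, :2]).query(nuclei[:, :2])
        return d <= radius

    pb, pc = positive(stain_b), positive(stain_c)
    table = ContingencyTable2x2(
        int(np.sum(pb & pc)),
        int(np.sum(pb & ~pc)),
        int(np.sum(~pb & pc)),
        int(np.sum(~pb & ~pc)),
    )
    oratio, p = fisher_exact_2x2(table)
    return ColocalizationResult(table=table, odds_ratio=oratio, p_value=p, radius=radius)


def count_top_regions(
    blobs: BlobSet,
    window_shape: tuple[int, int],
    image_shape: tuple[int, int],
    k: int = 3,
) -> float:
    """Mean blob count over the k highest-count non-overlapping windows.

    Greedy: place the best axis-aligned window, exclude overlapping
    placements, repeat. If fewer than k windows fit, the mean is taken over
    those that do (matching a slide with fewer fields than requested).
    """
    h, w = window_shape
    height, width = image_shape
    if h > height or w > width:
        raise ValueError("window does not fit in the image")
    blobs = np.asarray(blobs, dtype=float).reshape(-1, 3)
    if blobs.shape[0] == 0:
        return 0.0

    grid = np.zeros((height, width), dtype=np.int64)
    rr = np.clip(np.rint(blobs[:, 0]).astype(int), 0, height - 1)
    cc = np.clip(np.rint(blobs[:, 1]).astype(int), 0, width - 1)
    np.add.at(grid, (rr, cc), 1)

    # counts[i, j] = blobs in window with top-left (i, j), via 2D cumsum
    cs = np.zeros((height + 1, width + 1), dtype=np.int64)
    cs[1:, 1:] = grid.cumsum(0).cumsum(1)
    counts = (
        cs[h:, w:] - cs[:-h, w:] - cs[h:, :-w] + cs[:-h, :-w]
    ).astype(float)

    picks: list[int] = []
    n_pos_r, n_pos_c = counts.shape
    for _ in range(k):
        if np.all(np.isnan(counts)):
            break
        flat = np.nanargmax(counts)
        i, j = divmod(int(flat), n_pos_c)
        picks.append(int(counts[i, j]))
        r0, r1 = max(0, i - h + 1), min(n_pos_r, i + h)
        c0, c1 = max(0, j - w + 1), min(n_pos_c, j + w)
        counts[r0:r1, c0:c1] = np.nan
    if len(picks) < k:
        logger.warning("only %d of %d requested windows fit the image", len(picks), k)
    return float(np.mean(picks)) if picks else 0.0
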