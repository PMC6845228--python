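"""PC-dendrite segmentation: PCA-then-ICA spatial filters, mask building,
and trace extraction.

The movie (frames x pixels) is reduced by PCA, the retained temporal
components are unmixed by FastICA, and each independent component's spatial
filter is smoothed and thresholded into a candidate region.  Within a
candidate region only pixels whose time-courses correlate above 0.8 with
the region's mean time-course are kept, and pixels claimed by more than
one dendrite are removed from all masks.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from sklearn.decomposition import PCA

from .masks import PixelMask

logger = logging.getLogger(__name__)


def _orthomax_rotation(
    V: np.ndarray, gamma: float = 0.0, max_iter: int = 500, tol: float = 1e-4
) -> np.ndarray:
    """Orthogonal unmixing of loadings by quartic-contrast maximization.

    Rotates the orthonormal-column loadings ``V`` (pixels x components) to
    maximize the quartic sparsity contrast (gamma=0: quartimax, i.e. the
    kurtosis contrast of ICA under whitening; gamma=1: varimax).  Solved by
    the classical SVD fixed-point iteration, which is deterministic and,
    for sparse non-overlapping sources, reliably global.
    """
    p, k = V.shape
    R = np.eye(k)
    d_old = 0.0
    for _ in range(max_iter):
        L = V @ R
        u, s, vt = np.linalg.svd(
            V.T @ (L**3 - (gamma / p) * L * (L**2).sum(axis=0)),
            full_matrices=False,
        )
        R = u @ vt
        d = s.sum()
        if d_old != 0 and d < d_old * (1 + tol * 1e-2):
            break
        d_old = d
    return V @ R


class DimensionalityError(ValueError):
    """Movie rank insufficient for the requested number of components."""


@dataclass
class SpatialFilter:
    """Real-valued spatial weight image of one independent component."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        if not np.isfinite(self.weights).all():
            raise ValueError("filter weights must be finite")
        if not (np.abs(self.weights) > 0).any():
            raise ValueError("filter must have at least one non-zero pixel")


def pca_ica(
    movie: np.ndarray,
    n_components: int,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-4,
) -> list[SpatialFilter]:
    """Unmix a movie into spatially independent component filters.

    PCA (randomized, seeded) reduces pixels x time to ``n_components``
    spatial eigenimages; these are then unmixed into spatially independent
    sources by maximizing the quartic (kurtosis) ICA contrast over pixels
    under an orthogonal unmixing matrix, so each sparse, localized dendrite
    emerges as one filter.  Each filter is sign-fixed so its
    largest-|weight| pixel is positive.  Deterministic given the seed
    (which enters only through the randomized PCA solver).  Surplus
    components beyond the number of true sources simply absorb noise and
    die later in mask building.
    """
    if movie.ndim != 3:
        raise ValueError("movie must be (frames, rows, cols)")
    n_frames, h, w = movie.shape
    n_pixels = h * w
    if n_components > min(n_pixels, n_frames):
        raise DimensionalityError(
            f"n_components={n_components} exceeds min(n_pixels={n_pixels}, "
            f"n_frames={n_frames})"
        )
    X = movie.reshape(n_frames, n_pixels)
    if np.ptp(X) == 0:
        raise DimensionalityError("constant movie has no components to extract")
    pca = PCA(
        n_components=n_components, svd_solver="randomized", random_state=seed
    )
    pca.fit(X)
    ev = pca.explained_variance_
    if ev[0] <= 0 or (ev < 1e-12 * ev[0]).any():
        raise DimensionalityError(
            "movie rank below the requested number of components"
        )
    # rows of pca.components_ are orthonormal eigenimages; unmix over pixels
    spatial = _orthomax_rotation(
        pca.components_.T, gamma=0.0, max_iter=max_iter, tol=tol
    ).T  # (k, n_pixels)
    filters = []
    for row in spatial:
        img = row.reshape(h, w)
        peak = img.flat[np.argmax(np.abs(img))]
        if peak < 0:
            img = -img
        filters.append(SpatialFilter(weights=img))
    return filters


def filters_to_masks(
    filters: list[SpatialFilter],
    movie: np.ndarray,
    smooth_sigma: float = 1.0,
    weight_threshold_sd: float = 2.0,
    corr_threshold: float = 0.8,
    min_pixels: int = 5,
    reject_compactness: float | None = None,
) -> list[PixelMask]:
    """Threshold smoothed spatial filters into disjoint binary dendrite masks.

    Each filter is Gaussian-smoothed and thresholded at mean +
    ``weight_threshold_sd`` SD; candidate pixels whose time-courses
    correlate > ``corr_threshold`` with the candidate region's mean
    time-course are kept; pixels claimed by more than one mask are removed
    from all; masks below ``min_pixels`` are dropped.  With
    ``reject_compactness`` set, candidate regions more compact than the
    given area/perimeter^2 threshold (soma-like) are discarded.
    """
    if not filters:
        raise ValueError("filters must be non-empty")
    n_frames, h, w = movie.shape
    X = movie.reshape(n_frames, h * w)
    claimed: list[np.ndarray] = []
    for f in filters:
        sm = ndimage.gaussian_filter(f.weights, smooth_sigma)
        thr = sm.mean() + weight_threshold_sd * sm.std()
        cand = sm > thr
        if not cand.any():
            claimed.append(np.zeros(0, dtype=np.intp))
            continue
        if reject_compactness is not None:
            area = cand.sum()
            eroded = ndimage.binary_erosion(cand)
            perimeter = max(int(area - eroded.sum()), 1)
            if area / perimeter**2 > reject_compactness:
                claimed.append(np.zeros(0, dtype=np.intp))
                continue
        lin = np.nonzero(cand.ravel())[0]
        ts = X[:, lin]
        mean_ts = ts.mean(axis=1)
        mean_ts = mean_ts - mean_ts.mean()
        ts = ts - ts.mean(axis=0)
        denom = np.linalg.norm(ts, axis=0) * np.linalg.norm(mean_ts)
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = (ts * mean_ts[:, None]).sum(axis=0) / denom
        claimed.append(lin[np.nan_to_num(corr) > corr_threshold])

    counts = np.zeros(h * w, dtype=np.int32)
    for lin in claimed:
        counts[lin] += 1
    masks: list[PixelMask] = []
    next_id = 1
    for lin in claimed:
        keep = lin[counts[lin] == 1]  # drop pixels claimed by >1 filter
        if keep.size < min_pixels:
            if lin.size:
                logger.info("dropping mask with %d unshared pixels", keep.size)
            continue
        masks.append(
            PixelMask(rows=keep // w, cols=keep % w, id=next_id, shape=(h, w))
        )
        next_id += 1
    return masks


def extract_traces(movie: np.ndarray, masks: list[PixelMask]) -> list[np.ndarray]:
    """Per-dendrite fluorescence: the mean of each frame over the mask pixels."""
    traces = []
    for m in masks:
        if m.area == 0:
            raise ValueError(f"empty mask id={m.id}")
        traces.append(movie[:, m.rows, m.cols].mean(axis=1).astype(float))
    return traces
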