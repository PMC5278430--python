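"""Planform wing area from top-down photographs.

The wings of a set are photographed on a white background of known area
``S_b``.  The image is smoothed with an edge-preserving bilateral
filter, binarised by two-class k-means++ clustering of pixel
intensities, and the wing area follows from the pixel fraction:

    S_w = (N_w / N) * S_b

with ``N_w`` wing pixels out of ``N`` total.  The darker cluster is
labelled wing (dark wings on a white background) unless
``wings_bright=True``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Rec. 601 luminance weights used to collapse colour images.
LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])


class NoContrastError(RuntimeError):
    """Raised when an image has too little contrast to form two clusters."""


@dataclass
class SegmentationResult:
    """Binary wing mask plus the pixel counts entering the area formula."""

    mask: np.ndarray
    Nw: int
    N: int

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.Nw != int(self.mask.sum()) or self.N != self.mask.size:
            raise ValueError("pixel counts inconsistent with mask")


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Collapse an (H, W[, 3]) image to float64 grey in [0, 1]."""
    image = np.asarray(image)
    if np.issubdtype(image.dtype, np.integer):
        image = image.astype(np.float64) / np.iinfo(image.dtype).max
    if image.ndim == 3:
        image = image[..., :3] @ LUMA_WEIGHTS
    return image.astype(np.float64)


def segment_wings(
    image: np.ndarray,
    bilateral_params: tuple[float, float] | None = (3.0, 0.1),
    seed: int = 0,
    *,
    wings_bright: bool = False,
    n_restarts: int = 5,
) -> SegmentationResult:
    """Bilateral smoothing followed by 2-class k-means++ binarisation.

    ``bilateral_params`` is (spatial sigma in px, range sigma as a
    fraction of the intensity range); pass ``None`` to skip smoothing.
    k-means++ runs ``n_restarts`` times and the labelling with the best
    inertia is kept, making the result deterministic for a fixed seed.
    """
    from skimage.restoration import denoise_bilateral
    from sklearn.cluster import KMeans

    img = to_grayscale(image)
    if img.size == 0:
        raise ValueError("empty image")
    intensity_range = float(img.max() - img.min())
    if intensity_range < 1e-9:
        raise NoContrastError("constant image: no contrast to cluster")

    if bilateral_params is not None:
        sigma_spatial, range_frac = bilateral_params
        img = denoise_bilateral(
            img,
            sigma_color=range_frac * intensity_range,
            sigma_spatial=sigma_spatial,
        )

    values = img.reshape(-1, 1)
    km = KMeans(
        n_clusters=2, init="k-means++", n_init=n_restarts, random_state=seed
    ).fit(values)
    centres = km.cluster_centers_.ravel()
    wing_cluster = int(np.argmax(centres) if wings_bright else np.argmin(centres))
    mask = (km.labels_ == wing_cluster).reshape(img.shape)
    return SegmentationResult(mask=mask, Nw=int(mask.sum()), N=int(mask.size))


def estimate_area(seg: SegmentationResult, Sb: float) -> float:
    """Wing planform area: S_w = (N_w / N) * S_b."""
    if Sb <= 0:
        raise ValueError("background area must be positive")
    if seg.N == 0:
        raise ValueError("segmentation contains no pixels")
    return seg.Nw / seg.N * Sb


def wing_area_from_image(
    image: np.ndarray,
    Sb: float,
    bilateral_params: tuple[float, float] | None = (3.0, 0.1),
    seed: int = 0,
    **kwargs,
) -> tuple[float, SegmentationResult]:
    """Convenience wrapper: segment then convert pixel fraction to area."""
    seg = segment_wings(image, bilateral_params, seed, **kwargs)
    return estimate_area(seg, Sb), seg
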