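"""Tissue segmentation, colour normalisation and patch extraction.

Mirrors the standard TMA-core preprocessing chain: a 2-component Gaussian
mixture on per-pixel luminance separates tissue from the near-white glass
background; every core is colour-normalised to one manually chosen reference
core by per-channel 128-bin histogram matching; square patches are then
extracted on a raster grid and kept only if at least half their area is
tissue.
"""

from __future__ import annotations

import warnings

import numpy as np
from PIL import Image

from .types import CoreImage, Patch, TissueMask

__all__ = [
    "N_BINS", "segment_tissue", "build_reference", "normalize_to_reference",
    "extract_patches", "luminance", "read_core", "write_core",
    "write_mask", "ReferenceHistogram",
]

#: histogram resolution used for colour normalisation
N_BINS = 128
_BIN_WIDTH = 256 // N_BINS  # 2 intensity levels per bin


def luminance(pixels: np.ndarray) -> np.ndarray:
    """Rec.601 luma of an H x W x 3 array."""
    p = np.asarray(pixels, dtype=np.float64)
    return 0.299 * p[..., 0] + 0.587 * p[..., 1] + 0.114 * p[..., 2]


def _em_gmm_1d(x: np.ndarray, max_iter: int, tol: float):
    """2-component univariate Gaussian mixture fitted by EM.

    Means start at the 25th/75th percentiles with equal weights and a
    common initial spread of a quarter of the inter-percentile distance,
    which anchors one component on the bright background mode and one on
    the darker tissue values; iteration stops when the relative
    log-likelihood change drops below ``tol``.
    """
    mu = np.percentile(x, [25.0, 75.0]).astype(np.float64)
    sd = np.full(2, max((mu[1] - mu[0]) / 4.0, 1e-3))
    w = np.array([0.5, 0.5])
    prev_ll = -np.inf
    for _ in range(max_iter):
        logp = (-0.5 * ((x[:, None] - mu) / sd) ** 2
                - np.log(sd) + np.log(w))
        m = logp.max(axis=1, keepdims=True)
        p = np.exp(logp - m)
        tot = p.sum(axis=1, keepdims=True)
        resp = p / tot
        ll = float(np.sum(m.ravel() + np.log(tot.ravel())))
        nk = resp.sum(axis=0)
        w = nk / len(x)
        mu = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - mu) ** 2).sum(axis=0) / nk
        sd = np.sqrt(np.maximum(var, 1e-6))
        if abs(ll - prev_ll) < tol * max(abs(ll), 1.0):
            break
        prev_ll = ll
    return mu, sd, w


def segment_tissue(image: CoreImage, max_iter: int = 100,
                   tol: float = 1e-4) -> TissueMask:
    """Tissue/background mask from a 2-class Gaussian mixture on luminance.

    The mixture is fitted by EM initialised at the 25th/75th luminance
    percentiles; the component with the lower mean is tissue (H&E tissue is
    darker than glass) and the mask is the per-pixel MAP assignment, so the
    result is invariant to component-label permutation.  A degenerate image
    (all pixels identical) yields an all-background mask flagged degenerate.
    """
    lum = luminance(image.pixels).ravel()
    if np.ptp(lum) == 0:
        warnings.warn("degenerate image: all pixels identical; "
                      "returning empty tissue mask")
        return TissueMask(np.zeros(image.pixels.shape[:2], dtype=bool),
                          degenerate=True)
    mu, sd, w = _em_gmm_1d(lum, max_iter=max_iter, tol=tol)
    logp = (-0.5 * ((lum[:, None] - mu) / sd) ** 2
            - np.log(sd) + np.log(w))
    labels = logp.argmax(axis=1)
    tissue_component = int(np.argmin(mu))
    mask = (labels == tissue_component).reshape(image.pixels.shape[:2])
    return TissueMask(mask)


class ReferenceHistogram:
    """Per-channel 128-bin intensity histogram of a reference core."""

    def __init__(self, counts: np.ndarray, core_id: str = ""):
        counts = np.asarray(counts, dtype=np.int64)
        if counts.shape != (3, N_BINS):
            raise ValueError(f"expected shape (3, {N_BINS})")
        if (counts < 0).any():
            raise ValueError("negative histogram counts")
        self.counts = counts
        self.core_id = core_id

    def cdf(self) -> np.ndarray:
        """Per-channel normalised cumulative distribution (3 x 128)."""
        c = np.cumsum(self.counts, axis=1).astype(np.float64)
        totals = c[:, -1:].copy()
        totals[totals == 0] = 1.0
        return c / totals


def build_reference(image: CoreImage) -> ReferenceHistogram:
    """128-bin per-channel histogram of the full core."""
    counts = np.stack([
        np.bincount(image.pixels[..., ch].ravel() // _BIN_WIDTH,
                    minlength=N_BINS)
        for ch in range(3)
    ])
    return ReferenceHistogram(counts, core_id=image.core_id)


def _match_channel(values: np.ndarray, ref_cdf: np.ndarray) -> np.ndarray:
    """Map one uint8 channel onto a reference CDF through 128-bin matching."""
    bins = values // _BIN_WIDTH
    counts = np.bincount(bins.ravel(), minlength=N_BINS)
    cdf = np.cumsum(counts).astype(np.float64)
    cdf /= max(cdf[-1], 1.0)
    # smallest reference bin whose CDF reaches the input bin's CDF
    # (searchsorted 'left' breaks ties toward the lower bin)
    mapping = np.searchsorted(ref_cdf, cdf - 1e-12, side="left")
    mapping = np.clip(mapping, 0, N_BINS - 1)
    out_values = (mapping * _BIN_WIDTH + _BIN_WIDTH // 2 - 1).astype(np.uint8)
    return out_values[bins]


def normalize_to_reference(image: CoreImage,
                           ref: ReferenceHistogram) -> CoreImage:
    """Per-channel monotone histogram matching to the reference template.

    Each 128-bin quantile of the input channel's CDF is mapped to the
    reference channel's CDF (piecewise-constant inverse, ties toward the
    lower bin); output stays 8-bit.  Matching an image against its own
    histogram changes no pixel by more than one bin width.
    """
    ref_cdf = ref.cdf()
    out = np.stack([
        _match_channel(image.pixels[..., ch], ref_cdf[ch])
        for ch in range(3)
    ], axis=-1)
    return CoreImage(out, patient_id=image.patient_id, core_id=image.core_id)


def extract_patches(image: CoreImage, mask: TissueMask, size: int = 256,
                    stride: int | None = None, min_tissue: float = 0.5,
                    weak_label: str = "unlabeled") -> list[Patch]:
    """Raster-scan patch extraction with a tissue-area filter.

    Windows start at (0, 0) and advance by ``stride`` (default: ``size``,
    i.e. non-overlapping; pass ``size // 2`` for the 50%-overlap inference
    tiling); incomplete boundary windows are dropped, and a window is kept
    only if its tissue fraction is at least ``min_tissue``.
    """
    H, W = image.pixels.shape[:2]
    if stride is None:
        stride = size
    if not 0 < stride <= size:
        raise ValueError("need 0 < stride <= size")
    if size > min(H, W):
        warnings.warn(f"patch size {size} exceeds image {H}x{W}; "
                      "no patches extracted")
        return []
    if mask.mask.shape != (H, W):
        raise ValueError("mask shape does not match image")
    # integral image makes per-window tissue fractions O(1)
    integral = np.pad(np.cumsum(np.cumsum(mask.mask, axis=0), axis=1),
                      ((1, 0), (1, 0)))
    patches = []
    for r in range(0, H - size + 1, stride):
        for c in range(0, W - size + 1, stride):
            n_tissue = (integral[r + size, c + size] - integral[r, c + size]
                        - integral[r + size, c] + integral[r, c])
            frac = n_tissue / (size * size)
            if frac >= min_tissue:
                patches.append(Patch(
                    pixels=image.pixels[r:r + size, c:c + size].copy(),
                    tissue_fraction=float(frac), core_id=image.core_id,
                    row=r, col=c, patient_id=image.patient_id,
                    weak_label=weak_label))
    return patches


# ---------------------------------------------------------------------------
# image i/o
# ---------------------------------------------------------------------------

def read_core(path, patient_id: str = "", core_id: str = "") -> CoreImage:
    arr = np.asarray(Image.open(path).convert("RGB"))
    return CoreImage(arr, patient_id=patient_id, core_id=core_id)


def write_core(path, image: CoreImage) -> None:
    Image.fromarray(image.pixels, mode="RGB").save(path)


def write_mask(path, mask: TissueMask) -> None:
    Image.fromarray((mask.mask * 255).astype(np.uint8), mode="L").save(path)
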