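"""Rotational/translational/mirror 2D image alignment by FFT cross-correlation.

The correlation is computed between images that are masked by a centered
circular mask (radius 30 px of 32), zero-meaned within the mask and
normalized to unit power; the translational optimum for each candidate
rotation is found by FFT cross-correlation restricted to a maximum shift.

Sign conventions (documented and tested):

* ``psi`` is the counterclockwise in-plane rotation (degrees, array axes
  ``(0, 1)`` via ``scipy.ndimage.rotate``) applied to the *query* before
  correlation: if the query is the reference rotated by +30 degrees, the
  recovered psi is -30.
* ``shift`` is the (dx, dy) in pixels applied to the rotated query so it
  matches the reference: a query equal to the reference shifted by
  (+5, -3) px recovers shift (-5, +3)... i.e. the shift that undoes it.
* ``mirrored`` means the query was flipped along its first axis before
  rotation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numpy.fft import irfft2, rfft2
from scipy import ndimage

from shapesearch.errors import UndefinedCorrelationError
from shapesearch.projections import IMAGE_SIZE, ImageStack, ProjectionImage

logger = logging.getLogger(__name__)

#: Radius of the centered circular correlation mask, pixels.
MASK_RADIUS = 30.0


@dataclass
class Alignment2DResult:
    """Best in-plane alignment of a query against a reference."""

    psi: float
    shift: tuple[int, int]
    mirrored: bool
    cc_max: float


def _circular_mask(n: int = IMAGE_SIZE, radius: float = MASK_RADIUS) -> np.ndarray:
    c = (n - 1) / 2.0
    yy, xx = np.meshgrid(np.arange(n) - c, np.arange(n) - c, indexing="ij")
    return (xx**2 + yy**2) <= radius**2


def _prepare(pixels: np.ndarray, mask: np.ndarray, strict: bool = True) -> np.ndarray | None:
    """Mask, zero-mean within the mask and normalize to unit power."""
    m = pixels * mask
    mean = m[mask].mean()
    m = (pixels - mean) * mask
    norm = np.sqrt((m**2).sum())
    if norm <= 1e-12 * max(1.0, abs(mean)) or norm == 0.0:
        if strict:
            raise UndefinedCorrelationError("constant image within correlation mask")
        return None
    return m / norm


def _shift_window(n: int, max_shift: int) -> np.ndarray:
    """Boolean mask over the wrapped correlation map for |shift| <= max_shift."""
    freq = np.fft.fftfreq(n, d=1.0 / n)
    ok = np.abs(freq) <= max_shift
    return np.outer(ok, ok)


def _wrapped_shift(index: int, n: int) -> int:
    return index if index <= n // 2 else index - n


def _rotated_queries(pixels: np.ndarray, psi_step: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All (psi, mirror) variants of an image, bilinear interpolation.

    Returns (variants, psis, mirrors) with variants of shape (R, n, n).
    """
    psis = np.arange(0.0, 360.0, psi_step)
    variants, out_psis, out_mirror = [], [], []
    for mirrored in (False, True):
        base = pixels[::-1, :] if mirrored else pixels
        for psi in psis:
            if psi == 0.0:
                rot = base
            else:
                rot = ndimage.rotate(base, psi, axes=(0, 1), reshape=False, order=1, mode="constant", cval=0.0)
            variants.append(rot)
            out_psis.append(psi)
            out_mirror.append(mirrored)
    return np.stack(variants), np.asarray(out_psis), np.asarray(out_mirror)


def align_pair(
    query: ProjectionImage,
    ref: ProjectionImage,
    psi_step: float = 2.0,
    max_shift: int = 10,
) -> Alignment2DResult:
    """Exhaustively align a query to a reference over rotation/shift/mirror.

    For every psi in {0, psi_step, ..., 360 - psi_step} and mirror state the
    rotated query is correlated with the reference by FFT; the global
    maximum over shifts with |dx|, |dy| <= max_shift is returned.

    Raises
    ------
    UndefinedCorrelationError
        If either image is constant within the correlation mask.
    """
    if psi_step <= 0:
        raise ValueError("psi_step must be positive")
    n = IMAGE_SIZE
    mask = _circular_mask(n)
    ref_p = _prepare(ref.pixels, mask)
    f_ref = rfft2(ref_p)
    window = _shift_window(n, max_shift)

    variants, psis, mirrors = _rotated_queries(query.pixels, psi_step)
    best = None
    for var, psi, mirrored in zip(variants, psis, mirrors):
        q_p = _prepare(var, mask)
        # corr[u] = sum_x q(x) ref(x + u): peak u is the shift taking query onto ref
        corr = irfft2(np.conj(rfft2(q_p)) * f_ref, s=(n, n))
        corr = np.where(window, corr, -np.inf)
        idx = np.unravel_index(np.argmax(corr), corr.shape)
        cc = float(corr[idx])
        # ties within float noise keep the earliest (lowest psi, mirror off)
        if best is None or cc > best[0] + 1e-9:
            shift = (_wrapped_shift(idx[0], n), _wrapped_shift(idx[1], n))
            best = (cc, float(psi), shift, bool(mirrored))
    cc, psi, shift, mirrored = best
    return Alignment2DResult(psi=psi, shift=shift, mirrored=mirrored, cc_max=cc)


def align_stack_to_reference(
    ref: ProjectionImage,
    stack: ImageStack,
    psi_step: float = 2.0,
    max_shift: int = 10,
) -> np.ndarray:
    """Maximum CC of every stack image against a fixed reference.

    The rotation search is carried by the (single) reference image, which
    is equivalent to rotating each stack image up to the sign of the
    recovered angle and interpolation asymmetry; only ``cc_max`` values are
    returned, one per stack image in stack order.  A constant stack image
    is recorded as NaN with a warning instead of aborting the run.
    """
    if len(stack) == 0:
        raise ValueError("empty stack")
    n = IMAGE_SIZE
    mask = _circular_mask(n)
    window = _shift_window(n, max_shift)

    variants, _, _ = _rotated_queries(ref.pixels, psi_step)
    prepped = []
    for var in variants:
        p = _prepare(var, mask, strict=False)
        if p is None:
            raise UndefinedCorrelationError("reference image is constant within mask")
        prepped.append(p)
    f_refs = rfft2(np.stack(prepped), axes=(-2, -1))  # (R, n, n//2+1)

    out = np.empty(len(stack))
    for i, im in enumerate(stack):
        p = _prepare(im.pixels, mask, strict=False)
        if p is None:
            logger.warning("stack image %d is constant within mask; recording NaN", i)
            out[i] = np.nan
            continue
        f_img = rfft2(p)
        corr = irfft2(np.conj(f_refs) * f_img[None], s=(n, n), axes=(-2, -1))
        out[i] = corr[:, window].max()
    return out
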