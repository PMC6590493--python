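"""H&E stain estimation, normalization, and stain-space color augmentation.

Stain mixing is linear in optical density (OD): for a pixel with incident
intensity I0 and transmitted intensity I, ``OD = -log10(I / I0)`` and the
OD vector is a nonnegative combination of the hematoxylin (H) and eosin (E)
direction vectors.  The per-image stain directions are estimated from the
plane spanned by the top two singular vectors of the foreground OD pixels
(the classic SVD-based estimator): foreground OD pixels are projected onto
that plane and the stain vectors are read off at extreme angular
percentiles.  Normalization deconvolves the image against its own profile,
rescales the two concentration maps to a fixed reference scale and
reconstructs the patch with the package reference stain vectors, so that
patches from different scanners and staining batches share one color basis.

Augmentation perturbs the H and E concentration maps multiplicatively
(factors drawn uniformly from [0.7, 1.3]) and reconstructs with the image's
*own* profile, which varies stain intensity without moving tissue.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml

from .errors import DegenerateImageError, InvalidInputError, InvalidParameterError

logger = logging.getLogger(__name__)

#: Incident light intensity; with the +1 offset this keeps log arguments in
#: (0, 1] for uint8 data and makes the RGB<->OD round trip exact.
I0 = 256.0

#: Default OD threshold below which a pixel is treated as background.
DEFAULT_BETA = 0.15

#: Default angular percentile for reading off the extreme stain directions.
DEFAULT_ALPHA = 1.0

_MIN_FOREGROUND = 100


@dataclass(frozen=True)
class StainProfile:
    """Per-image H&E stain basis.

    Attributes
    ----------
    stain_matrix:
        (2, 3) array of unit row vectors; row 0 is hematoxylin (identified
        as the direction with the larger blue-channel OD loading), row 1
        is eosin.
    max_concentrations:
        Robust (99th percentile) per-stain concentration scale, length 2.
    """

    stain_matrix: np.ndarray
    max_concentrations: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.stain_matrix, dtype=float)
        c = np.asarray(self.max_concentrations, dtype=float)
        if m.shape != (2, 3):
            raise InvalidInputError(f"stain_matrix must be 2x3, got {m.shape}")
        if np.any(m < -1e-9):
            raise InvalidInputError("stain vectors must be nonnegative")
        if not np.allclose(np.linalg.norm(m, axis=1), 1.0, atol=1e-6):
            raise InvalidInputError("stain vectors must have unit norm")
        if c.shape != (2,) or np.any(c < 0):
            raise InvalidInputError("max_concentrations must be 2 nonnegative scalars")
        object.__setattr__(self, "stain_matrix", m)
        object.__setattr__(self, "max_concentrations", c)


#: The fixed normalization target shares the StainProfile contract.
ReferenceStain = StainProfile


def load_reference_stain(path: str | None = None) -> ReferenceStain:
    """Load the package reference stain, or one from a user YAML file.

    The YAML schema is ``stain_matrix`` (2 rows of 3) and
    ``max_concentrations`` (2 scalars); rows are renormalized to unit length.
    """
    if path is None:
        text = (
            resources.files("cellquant")
            .joinpath("config/reference_stain.yaml")
            .read_text()
        )
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    m = np.asarray(raw["stain_matrix"], dtype=float)
    m = m / np.linalg.norm(m, axis=1, keepdims=True)
    return ReferenceStain(m, np.asarray(raw["max_concentrations"], dtype=float))


def _check_rgb(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise InvalidInputError(
            f"expected an H x W x 3 RGB image, got shape {image.shape}"
        )
    return image


def rgb_to_od(image: np.ndarray) -> np.ndarray:
    """Convert an RGB uint8 image to optical density.

    OD = -log10((I + 1) / I0) with I0 = 256; the +1 offset avoids log(0)
    and makes :func:`od_to_rgb` an exact inverse on uint8 input.
    """
    image = _check_rgb(image)
    if np.issubdtype(image.dtype, np.floating):
        if image.min() < 0 or image.max() > 255:
            raise InvalidInputError("pixel values must lie in [0, 255]")
    return -np.log10((image.astype(np.float64) + 1.0) / I0)


def od_to_rgb(od: np.ndarray) -> np.ndarray:
    """Invert :func:`rgb_to_od`, rounding and clipping to uint8."""
    od = np.asarray(od, dtype=np.float64)
    intensity = I0 * np.power(10.0, -od) - 1.0
    return np.clip(np.rint(intensity), 0, 255).astype(np.uint8)


def _foreground_od(od_flat: np.ndarray, beta: float) -> np.ndarray:
    norms = np.linalg.norm(od_flat, axis=1)
    return od_flat[norms > beta]


def estimate_stain_profile(
    od: np.ndarray,
    beta: float = DEFAULT_BETA,
    alpha: float = DEFAULT_ALPHA,
) -> StainProfile:
    """Estimate the H and E stain vectors of one image from its OD pixels.

    Parameters
    ----------
    od:
        H x W x 3 (or N x 3) optical-density array.
    beta:
        Foreground threshold: pixels with OD norm <= beta are background.
    alpha:
        Angular percentile; the stain vectors are taken at the alpha-th and
        (100 - alpha)-th percentile angles inside the top-2 singular plane.

    Raises
    ------
    DegenerateImageError
        Fewer than 100 foreground pixels, or an effectively rank-1 OD cloud
        (single pure stain), for which two directions cannot be identified.
    """
    od = np.asarray(od, dtype=np.float64)
    od_flat = od.reshape(-1, 3)
    fg = _foreground_od(od_flat, beta)
    if fg.shape[0] < _MIN_FOREGROUND:
        raise DegenerateImageError(
            f"only {fg.shape[0]} foreground pixels (need >= {_MIN_FOREGROUND})"
        )

    # Plane of the top two right-singular vectors of the foreground cloud.
    _, s, vt = np.linalg.svd(fg, full_matrices=False)
    # Quantization noise keeps the second singular value of even a pure
    # single-stain image slightly above zero; a relative threshold of 1%
    # separates that regime from genuine two-stain clouds by two orders of
    # magnitude.
    if s[0] <= 0 or s[1] / s[0] < 1e-2:
        raise DegenerateImageError("OD cloud is effectively rank 1 (single stain)")
    basis = vt[:2]  # (2, 3)
    # Orient the basis so projections land in the positive half plane.
    for i in range(2):
        if basis[i].sum() < 0:
            basis[i] = -basis[i]

    proj = fg @ basis.T  # (N, 2)
    phi = np.arctan2(proj[:, 1], proj[:, 0])
    lo, hi = np.percentile(phi, [alpha, 100.0 - alpha])
    if hi - lo < np.radians(2.0):
        raise DegenerateImageError("angular spread too small to separate two stains")
    v_lo = np.cos(lo) * basis[0] + np.sin(lo) * basis[1]
    v_hi = np.cos(hi) * basis[0] + np.sin(hi) * basis[1]

    vectors = []
    for v in (v_lo, v_hi):
        v = np.where(v < 0, 0.0, v)  # tiny negatives from percentile cut
        n = np.linalg.norm(v)
        if n < 1e-12:
            raise DegenerateImageError("degenerate stain direction")
        vectors.append(v / n)
    # Hematoxylin has the larger blue-channel OD loading.
    if vectors[0][2] < vectors[1][2]:
        vectors = vectors[::-1]
    stain_matrix = np.vstack(vectors)

    conc = stain_concentrations(fg, stain_matrix)
    max_c = np.percentile(conc, 99, axis=0)
    max_c = np.maximum(max_c, 1e-12)
    return StainProfile(stain_matrix, max_c)


def stain_concentrations(od: np.ndarray, stain_matrix: np.ndarray) -> np.ndarray:
    """Per-pixel nonnegative least-squares stain concentrations.

    Solves min ||od - c_h * H - c_e * E||^2 with c >= 0 for every pixel,
    vectorized over pixels. For two stains the KKT cases are explicit: take
    the unconstrained 2x2 solution where it is feasible, otherwise the best
    single-stain projection clipped at zero.
    """
    od_flat = np.asarray(od, dtype=np.float64).reshape(-1, 3)
    h, e = stain_matrix[0], stain_matrix[1]
    g_hh, g_ee, g_he = h @ h, e @ e, h @ e
    b_h, b_e = od_flat @ h, od_flat @ e
    det = g_hh * g_ee - g_he**2
    if det < 1e-12:
        raise DegenerateImageError("stain vectors are collinear")

    c_h = (g_ee * b_h - g_he * b_e) / det
    c_e = (g_hh * b_e - g_he * b_h) / det
    conc = np.stack([c_h, c_e], axis=1)

    infeasible = (c_h < 0) | (c_e < 0)
    if np.any(infeasible):
        bh, be = b_h[infeasible], b_e[infeasible]
        # Single-stain candidates (the other coefficient pinned at 0).
        ch_only = np.maximum(bh / g_hh, 0.0)
        ce_only = np.maximum(be / g_ee, 0.0)
        sq = np.einsum("ij,ij->i", od_flat[infeasible], od_flat[infeasible])
        res_h = sq - 2 * ch_only * bh + ch_only**2 * g_hh
        res_e = sq - 2 * ce_only * be + ce_only**2 * g_ee
        use_h = res_h <= res_e
        sub = np.zeros((infeasible.sum(), 2))
        sub[use_h, 0] = ch_only[use_h]
        sub[~use_h, 1] = ce_only[~use_h]
        conc[infeasible] = sub
    return conc


def normalize_stain(
    image: np.ndarray,
    reference: ReferenceStain | None = None,
    beta: float = DEFAULT_BETA,
    alpha: float = DEFAULT_ALPHA,
) -> np.ndarray:
    """Map an H&E patch onto the reference stain basis.

    Concentrations are solved against the image's own estimated profile,
    rescaled by ``reference.max_concentrations / profile.max_concentrations``
    and reconstructed with the reference stain vectors.  Degenerate patches
    (nearly unstained, or single-stain) are returned unchanged with a
    logged warning — patches at cellularity 0 may be nearly blank.
    """
    image = _check_rgb(image)
    if reference is None:
        reference = load_reference_stain()
    od = rgb_to_od(image)
    try:
        profile = estimate_stain_profile(od, beta=beta, alpha=alpha)
    except DegenerateImageError as exc:
        logger.warning("stain normalization skipped: %s", exc)
        return image.copy()
    conc = stain_concentrations(od, profile.stain_matrix)
    conc *= reference.max_concentrations / profile.max_concentrations
    od_new = conc @ reference.stain_matrix
    return od_to_rgb(od_new.reshape(image.shape))


def augment_he(
    image: np.ndarray,
    factors: tuple[float, float] | None = None,
    rng_seed: int | None = None,
    beta: float = DEFAULT_BETA,
    alpha: float = DEFAULT_ALPHA,
) -> np.ndarray:
    """Stain-space color augmentation.

    The H and E concentration maps are each multiplied by a factor in
    [0.7, 1.3] (drawn uniformly from ``rng_seed`` when not given) and the
    image is reconstructed with its own stain profile.
    """
    image = _check_rgb(image)
    if factors is None:
        rng = np.random.default_rng(rng_seed)
        factors = tuple(rng.uniform(0.7, 1.3, size=2))
    factors = np.asarray(factors, dtype=float)
    if factors.shape != (2,) or np.any(factors < 0.7) or np.any(factors > 1.3):
        raise InvalidParameterError(
            f"augmentation factors must be 2 scalars in [0.7, 1.3], got {factors}"
        )
    od = rgb_to_od(image)
    try:
        profile = estimate_stain_profile(od, beta=beta, alpha=alpha)
    except DegenerateImageError as exc:
        logger.warning("stain augmentation skipped: %s", exc)
        return image.copy()
    conc = stain_concentrations(od, profile.stain_matrix) * factors
    od_new = conc @ profile.stain_matrix
    return od_to_rgb(od_new.reshape(image.shape))
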