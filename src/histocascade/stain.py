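"""Colour deconvolution of H&E-stained RGB images.

Transmitted light through a stained section follows the Beer-Lambert law:
the optical density (OD) in each colour channel, ``a = -log10(I / I0)``, is
linear in the amount of absorbing stain.  Each stain has a characteristic
unit OD colour vector; stacking the vectors for hematoxylin, eosin and a
residual third material gives a normalized 3x3 stain matrix ``M`` (rows =
stains, columns = R, G, B).  A pixel carrying stain amounts ``C`` then shows
OD ``a = C @ M``, and the amounts are recovered by ``C = a @ inv(M)``.

The hematoxylin plane of the unmixed image highlights nuclear material and
is the input to nuclei detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError

__all__ = [
    "StainMatrix",
    "default_he_matrix",
    "to_optical_density",
    "deconvolve",
    "compose",
    "hematoxylin_channel",
    "quantize",
]

#: Widely used unit OD colour vectors for hematoxylin and eosin
#: (Ruifrok-style calibration of standard H&E staining).
_HEMATOXYLIN_OD = (0.650, 0.704, 0.286)
_EOSIN_OD = (0.072, 0.990, 0.105)

#: Condition number above which a stain matrix is treated as singular.
_MAX_CONDITION = 1e8


@dataclass(frozen=True)
class StainMatrix:
    """Normalized 3x3 stain matrix plus incident light intensity.

    Row 0 is hematoxylin, row 1 eosin, row 2 the residual material; each
    row has unit Euclidean norm.  ``i0`` is the incident light intensity
    per channel (255 for 8-bit images).
    """

    matrix: np.ndarray
    i0: float = 255.0
    hematoxylin_row: int = 0

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise ConfigurationError(f"stain matrix must be 3x3, got {m.shape}")
        norms = np.linalg.norm(m, axis=1)
        if np.any(norms <= 0):
            raise ConfigurationError("stain matrix has a zero row")
        m = m / norms[:, None]
        cond = np.linalg.cond(m)
        if not np.isfinite(cond) or cond > _MAX_CONDITION:
            raise ConfigurationError(
                f"stain matrix is singular or ill-conditioned (cond={cond:.3g})"
            )
        if self.i0 <= 0:
            raise ConfigurationError("incident intensity i0 must be positive")
        m.flags.writeable = False
        object.__setattr__(self, "matrix", m)

    @property
    def inverse(self) -> np.ndarray:
        return np.linalg.inv(self.matrix)

    @classmethod
    def from_stains(
        cls,
        hematoxylin=_HEMATOXYLIN_OD,
        eosin=_EOSIN_OD,
        residual=None,
        i0: float = 255.0,
    ) -> "StainMatrix":
        """Build a matrix from H and E OD vectors, completing the third
        (residual) row with their normalized cross product when omitted."""
        h = np.asarray(hematoxylin, dtype=float)
        e = np.asarray(eosin, dtype=float)
        if residual is None:
            r = np.cross(h, e)
            nr = np.linalg.norm(r)
            if nr == 0:
                raise ConfigurationError("hematoxylin and eosin vectors are parallel")
            r = r / nr
        else:
            r = np.asarray(residual, dtype=float)
        return cls(matrix=np.stack([h, e, r]), i0=i0)

    @classmethod
    def from_flat(cls, values, i0: float = 255.0) -> "StainMatrix":
        """Nine numbers, row-major (H row, E row, residual row)."""
        v = np.asarray(values, dtype=float)
        if v.size != 9:
            raise ConfigurationError("expected nine matrix entries")
        return cls(matrix=v.reshape(3, 3), i0=i0)


def default_he_matrix(i0: float = 255.0) -> StainMatrix:
    """Default H&E stain matrix with a cross-product residual row."""
    return StainMatrix.from_stains(i0=i0)


def to_optical_density(image: np.ndarray, i0: float = 255.0) -> np.ndarray:
    """Per-channel OD transform ``a = -log10(I / i0)``.

    Zero intensities are clamped to ``eps = 1/i0`` before the log so the
    OD of a saturated dark pixel is finite (``2*log10(i0)`` for i0=255).
    """
    if i0 <= 0:
        raise ConfigurationError("incident intensity i0 must be positive")
    img = np.asarray(image, dtype=float)
    eps = 1.0 / i0
    return -np.log10(np.maximum(img, eps) / i0)


def od_clamp_ceiling(i0: float = 255.0) -> float:
    """The documented OD value assigned to zero-intensity pixels."""
    return -np.log10((1.0 / i0) / i0)


def compose(stains: np.ndarray, matrix: StainMatrix) -> np.ndarray:
    """Forward Beer-Lambert model: stain amounts -> float RGB intensities.

    ``a = C @ M`` and ``I = i0 * 10**(-a)``.  Output is continuous; use
    :func:`quantize` to emulate an 8-bit scanner.
    """
    c = np.asarray(stains, dtype=float)
    od = c @ matrix.matrix
    return matrix.i0 * np.power(10.0, -od)


def deconvolve(od: np.ndarray, matrix: StainMatrix) -> np.ndarray:
    """Unmix per-pixel stain amounts: ``C = a @ inv(M)``.

    Accepts any array whose last axis has length 3 (an OD image or a flat
    list of OD triplets); the output has the same shape.
    """
    a = np.asarray(od, dtype=float)
    if a.shape[-1] != 3:
        raise ConfigurationError("OD array must have three channels on the last axis")
    return a @ matrix.inverse


def hematoxylin_channel(stain_image: np.ndarray, matrix: StainMatrix | None = None) -> np.ndarray:
    """Extract the hematoxylin plane, clipping negative unmixing noise to 0."""
    row = 0 if matrix is None else matrix.hematoxylin_row
    plane = np.asarray(stain_image, dtype=float)[..., row]
    return np.clip(plane, 0.0, None)


def quantize(image: np.ndarray, i0: float = 255.0) -> np.ndarray:
    """Round and clip a float intensity image to 8-bit."""
    return np.clip(np.rint(image), 0, min(255, int(round(i0)))).astype(np.uint8)
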