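"""Per-pixel texture feature images and their tile-level aggregates.

Three families are computed on the hue, saturation and intensity channels
of the RGB tile, each as a stack of per-pixel feature images that are then
aggregated by (mean, population std, histogram mode):

* 15 first-order statistics: sliding-window mean / median / std / range,
  four Sobel orientations, three Kirsch compass responses, horizontal and
  vertical central-difference gradients, their difference, and a diagonal
  derivative.
* 21 grey-level co-occurrence (GLCM) statistics per pixel, from a
  symmetric, normalized 256-level co-occurrence matrix accumulated over
  the pixel's local window (default 9x9, four unit displacements).
* A 12-filter Gabor bank (2 frequencies x 6 orientations), real and
  imaginary response planes (24 per channel).

Totals: 135 first-order + 189 co-occurrence + 216 Gabor = 540 features.

The co-occurrence stage works in two complementary passes.  Statistics
that are linear functionals of the GLCM (``sum over (i,j) of f(i,j) *
p(i,j)``) are windowed averages of per-pair images and are computed with
box filters.  The entropy family (energy, entropy, maximum probability,
marginal entropy, sum- and difference-entropy) genuinely needs the local
joint histogram and is computed by a numba kernel that slides the window
incrementally, maintaining the joint and marginal histograms together with
running values of ``sum c^2`` and ``sum c*ln(c)``.  The two information
measures of correlation reduce to the joint and marginal entropies because
for any joint distribution ``HXY1 = HXY2 = HX + HY``.  All entropies use
the natural logarithm.

Window convention: a pixel's co-occurrence window is the (clipped) square
box centred on it; a displaced pair is counted when its anchor pixel lies
in the box and its partner lies inside the image.  Pairs are accumulated
symmetrically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy import ndimage
from scipy.signal import fftconvolve
from skimage.color import rgb2hsv

from .errors import ConfigurationError

__all__ = [
    "ChannelSet",
    "GaborParams",
    "to_hsi",
    "first_order_images",
    "cooccurrence_images",
    "gabor_kernel",
    "default_gabor_bank",
    "gabor_images",
    "aggregate_plane",
    "texture_vector",
    "window_glcm",
    "glcm_stats_reference",
    "FIRST_ORDER_NAMES",
    "COOCCURRENCE_NAMES",
    "TEXTURE_FEATURE_NAMES",
    "DEFAULT_OFFSETS",
]

CHANNEL_NAMES = ("hue", "saturation", "intensity")

FIRST_ORDER_NAMES = (
    "mean",
    "median",
    "std",
    "range",
    "sobel_v",
    "sobel_h",
    "sobel_d1",
    "sobel_d2",
    "kirsch_n",
    "kirsch_ne",
    "kirsch_e",
    "grad_v",
    "grad_h",
    "grad_diff",
    "diag_deriv",
)

COOCCURRENCE_NAMES = (
    "autocorrelation",
    "contrast",
    "correlation",
    "cluster_prominence",
    "cluster_shade",
    "dissimilarity",
    "energy",
    "entropy",
    "homogeneity",
    "maximum_probability",
    "variance",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "difference_variance",
    "difference_entropy",
    "imc1",
    "imc2",
    "inverse_difference",
    "inverse_difference_normalized",
    "inverse_difference_moment_normalized",
)

#: Four unit displacements (0, 45, 90, 135 degrees in image coordinates),
#: accumulated symmetrically into one matrix.
DEFAULT_OFFSETS = ((0, 1), (1, 1), (1, 0), (1, -1))

N_LEVELS = 256


@dataclass(frozen=True)
class ChannelSet:
    """Hue, saturation, intensity planes rescaled to [0, 255]."""

    hue: np.ndarray
    saturation: np.ndarray
    intensity: np.ndarray

    def planes(self):
        return (self.hue, self.saturation, self.intensity)


def to_hsi(image: np.ndarray) -> ChannelSet:
    """Hue / saturation (hexcone model) and mean-RGB intensity, in [0, 255]."""
    rgb = np.asarray(image, dtype=float)
    if rgb.ndim != 3 or rgb.shape[-1] != 3:
        raise ConfigurationError("expected an RGB image with 3 channels")
    hsv = rgb2hsv(rgb / 255.0)
    return ChannelSet(
        hue=hsv[..., 0] * 255.0,
        saturation=hsv[..., 1] * 255.0,
        intensity=rgb.mean(axis=-1),
    )


# ---------------------------------------------------------------------------
# first-order statistics

_SOBEL_V = np.array([[1, 2, 1], [0, 0, 0], [-1, -2, -1]], dtype=float)
_SOBEL_H = _SOBEL_V.T
_SOBEL_D1 = np.array([[2, 1, 0], [1, 0, -1], [0, -1, -2]], dtype=float)
_SOBEL_D2 = np.array([[0, 1, 2], [-1, 0, 1], [-2, -1, 0]], dtype=float)
_KIRSCH_N = np.array([[5, 5, 5], [-3, 0, -3], [-3, -3, -3]], dtype=float)
_KIRSCH_NE = np.array([[-3, 5, 5], [-3, 0, 5], [-3, -3, -3]], dtype=float)
_KIRSCH_E = np.array([[-3, -3, 5], [-3, 0, 5], [-3, -3, 5]], dtype=float)
_DIAG = np.array([[-0.5, 0, 0], [0, 0, 0], [0, 0, 0.5]], dtype=float)


def first_order_images(plane: np.ndarray, window: int = 3) -> list[np.ndarray]:
    """The 15 first-order feature images (reflected-boundary padding)."""
    if window < 3 or window % 2 == 0:
        raise ConfigurationError("window must be odd and >= 3")
    f = np.asarray(plane, dtype=float)
    if window > min(f.shape):
        raise ConfigurationError("window larger than image")
    mode = "reflect"

    mean = ndimage.uniform_filter(f, size=window, mode=mode)
    median = ndimage.median_filter(f, size=window, mode=mode)
    sq_mean = ndimage.uniform_filter(f * f, size=window, mode=mode)
    std = np.sqrt(np.clip(sq_mean - mean * mean, 0.0, None))
    rng = ndimage.maximum_filter(f, size=window, mode=mode) - ndimage.minimum_filter(
        f, size=window, mode=mode
    )
    grad_v = ndimage.correlate1d(f, [-0.5, 0.0, 0.5], axis=0, mode=mode)
    grad_h = ndimage.correlate1d(f, [-0.5, 0.0, 0.5], axis=1, mode=mode)
    conv = lambda k: ndimage.correlate(f, k, mode=mode)
    return [
        mean,
        median,
        std,
        rng,
        conv(_SOBEL_V),
        conv(_SOBEL_H),
        conv(_SOBEL_D1),
        conv(_SOBEL_D2),
        conv(_KIRSCH_N),
        conv(_KIRSCH_NE),
        conv(_KIRSCH_E),
        grad_v,
        grad_h,
        grad_v - grad_h,
        conv(_DIAG),
    ]


# ---------------------------------------------------------------------------
# co-occurrence: incremental sliding-histogram kernel (entropy family)


@njit(cache=True)
def _apply_pair(a, b, sign, J, mx, ps, pd, occ, logt, scal):
    # joint matrix, symmetrized: cells (a, b) and (b, a)
    for k in range(2):
        i = a if k == 0 else b
        j = b if k == 0 else a
        idx = i * 256 + j
        c = J[idx]
        if sign > 0:
            J[idx] = c + 1
            scal[1] += 2 * c + 1
            scal[2] += logt[c + 1] - logt[c]
            if c > 0:
                occ[c] -= 1
            occ[c + 1] += 1
            if c + 1 > scal[6]:
                scal[6] = c + 1
        else:
            J[idx] = c - 1
            scal[1] -= 2 * c - 1
            scal[2] += logt[c - 1] - logt[c]
            occ[c] -= 1
            if c - 1 > 0:
                occ[c - 1] += 1
            if c == int(scal[6]) and occ[c] == 0:
                cur = int(scal[6])
                while cur > 0 and occ[cur] == 0:
                    cur -= 1
                scal[6] = cur
    # marginals (row marginal of the symmetric matrix)
    for v in (a, b):
        c = mx[v]
        mx[v] = c + sign
        scal[3] += logt[c + sign] - logt[c]
    # sum (i + j) and difference |i - j| distributions, step 2 per pair
    c = ps[a + b]
    ps[a + b] = c + 2 * sign
    scal[4] += logt[c + 2 * sign] - logt[c]
    d = a - b if a >= b else b - a
    c = pd[d]
    pd[d] = c + 2 * sign
    scal[5] += logt[c + 2 * sign] - logt[c]
    scal[0] += 2 * sign


@njit(cache=True)
def _column_pairs(plane, y0, y1, col, offs, sign, J, mx, ps, pd, occ, logt, scal):
    h, w = plane.shape
    for r in range(y0, y1 + 1):
        for k in range(offs.shape[0]):
            rr = r + offs[k, 0]
            cc = col + offs[k, 1]
            if 0 <= rr < h and 0 <= cc < w:
                _apply_pair(plane[r, col], plane[rr, cc], sign, J, mx, ps, pd, occ, logt, scal)


@njit(cache=True)
def _cooc_entropy_kernel(plane, hw, offs, logt, out):
    h, w = plane.shape
    J = np.zeros(65536, dtype=np.int32)
    mx = np.zeros(256, dtype=np.int32)
    ps = np.zeros(511, dtype=np.int32)
    pd = np.zeros(256, dtype=np.int32)
    occ = np.zeros(logt.shape[0], dtype=np.int32)
    scal = np.zeros(7, dtype=np.float64)
    for y in range(h):
        y0 = max(0, y - hw)
        y1 = min(h - 1, y + hw)
        # build the window for x = 0
        for col in range(0, min(w - 1, hw) + 1):
            _column_pairs(plane, y0, y1, col, offs, 1, J, mx, ps, pd, occ, logt, scal)
        for x in range(w):
            if x > 0:
                leave = x - 1 - hw
                if leave >= 0:
                    _column_pairs(plane, y0, y1, leave, offs, -1, J, mx, ps, pd, occ, logt, scal)
                enter = x + hw
                if enter <= w - 1:
                    _column_pairs(plane, y0, y1, enter, offs, 1, J, mx, ps, pd, occ, logt, scal)
            nn = scal[0]
            if nn <= 0:
                for t in range(6):
                    out[y, x, t] = 0.0
                continue
            ln_n = np.log(nn)
            energy = scal[1] / (nn * nn)
            entropy = ln_n - scal[2] / nn
            hx = ln_n - scal[3] / nn
            sum_ent = ln_n - scal[4] / nn
            diff_ent = ln_n - scal[5] / nn
            out[y, x, 0] = energy
            out[y, x, 1] = entropy if entropy > 0.0 else 0.0
            out[y, x, 2] = scal[6] / nn
            out[y, x, 3] = hx if hx > 0.0 else 0.0
            out[y, x, 4] = sum_ent if sum_ent > 0.0 else 0.0
            out[y, x, 5] = diff_ent if diff_ent > 0.0 else 0.0
        # tear the window down so the next row starts from a clean state
        x_last = w - 1
        for col in range(max(0, x_last - hw), w):
            _column_pairs(plane, y0, y1, col, offs, -1, J, mx, ps, pd, occ, logt, scal)
        for t in range(7):
            scal[t] = 0.0


def _box_sum(arr: np.ndarray, window: int) -> np.ndarray:
    # uniform_filter with zero padding: mean * window^2 == clipped box sum
    return ndimage.uniform_filter(arr, size=window, mode="constant", cval=0.0) * (
        window * window
    )


def _window_moments(plane: np.ndarray, window: int, offsets) -> dict[str, np.ndarray]:
    """Windowed expectations E[f(i, j)] of the symmetrized pair distribution,
    for every f needed by the moment-based GLCM statistics."""
    h, w = plane.shape
    a_img = plane.astype(np.float64)
    funcs = {
        "u1": lambda a, b: 0.5 * (a + b),
        "u2": lambda a, b: 0.5 * (a * a + b * b),
        "ij": lambda a, b: a * b,
        "s1": lambda a, b: a + b,
        "s2": lambda a, b: (a + b) ** 2,
        "s3": lambda a, b: (a + b) ** 3,
        "s4": lambda a, b: (a + b) ** 4,
        "d1": lambda a, b: np.abs(a - b),
        "d2": lambda a, b: (a - b) ** 2,
        "hom": lambda a, b: 1.0 / (1.0 + (a - b) ** 2),
        "invd": lambda a, b: 1.0 / (1.0 + np.abs(a - b)),
        "invdn": lambda a, b: 1.0 / (1.0 + np.abs(a - b) / N_LEVELS),
        "invdmn": lambda a, b: 1.0 / (1.0 + (a - b) ** 2 / (N_LEVELS * N_LEVELS)),
    }
    sums = {name: np.zeros((h, w)) for name in funcs}
    count = np.zeros((h, w))
    for dr, dc in offsets:
        valid = np.zeros((h, w))
        r0, r1 = max(0, -dr), min(h, h - dr)
        c0, c1 = max(0, -dc), min(w, w - dc)
        valid[r0:r1, c0:c1] = 1.0
        shifted = np.zeros((h, w))
        shifted[r0:r1, c0:c1] = a_img[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        count += _box_sum(valid, window)
        for name, fn in funcs.items():
            vals = fn(a_img, shifted) * valid
            sums[name] += _box_sum(vals, window)
    count = np.maximum(count, 1e-12)
    return {name: s / count for name, s in sums.items()}


def cooccurrence_images(
    plane: np.ndarray, window: int = 9, offsets=DEFAULT_OFFSETS
) -> list[np.ndarray]:
    """The 21 per-pixel GLCM statistic images, in the documented order."""
    if len(offsets) == 0:
        raise ConfigurationError("offset set must be non-empty")
    if window < 3 or window % 2 == 0:
        raise ConfigurationError("window must be odd and >= 3")
    p = np.asarray(plane)
    if p.dtype.kind == "f":
        p = np.rint(p)
    p = np.clip(p, 0, 255).astype(np.int64)
    hw = window // 2
    offs = np.asarray(offsets, dtype=np.int64).reshape(-1, 2)

    max_entries = 2 * offs.shape[0] * window * window + 4
    k = np.arange(max_entries, dtype=np.float64)
    logt = np.where(k > 0, k * np.log(np.maximum(k, 1.0)), 0.0)

    ent = np.zeros(p.shape + (6,), dtype=np.float64)
    _cooc_entropy_kernel(p, hw, offs, logt, ent)
    energy, entropy, maxprob, hx, sum_ent, diff_ent = np.moveaxis(ent, -1, 0)

    m = _window_moments(p, window, offs)
    mu = m["u1"]
    var = np.clip(m["u2"] - mu * mu, 0.0, None)
    corr = np.where(var > 1e-12, (m["ij"] - mu * mu) / np.maximum(var, 1e-12), 0.0)
    mm = 2.0 * mu
    shade = m["s3"] - 3 * mm * m["s2"] + 3 * mm**2 * m["s1"] - mm**3
    prom = m["s4"] - 4 * mm * m["s3"] + 6 * mm**2 * m["s2"] - 4 * mm**3 * m["s1"] + mm**4
    sum_var = np.clip(m["s2"] - m["s1"] ** 2, 0.0, None)
    diff_var = np.clip(m["d2"] - m["d1"] ** 2, 0.0, None)
    # HXY1 = HXY2 = HX + HY = 2 HX for a symmetric GLCM
    imc1 = np.where(hx > 1e-12, (entropy - 2.0 * hx) / np.maximum(hx, 1e-12), 0.0)
    imc2 = np.sqrt(np.clip(1.0 - np.exp(-2.0 * (2.0 * hx - entropy)), 0.0, None))

    planes = [
        m["ij"],
        m["d2"],
        corr,
        prom,
        shade,
        m["d1"],
        energy,
        entropy,
        m["hom"],
        maxprob,
        var,
        m["s1"],
        sum_var,
        sum_ent,
        diff_var,
        diff_ent,
        imc1,
        imc2,
        m["invd"],
        m["invdn"],
        m["invdmn"],
    ]
    assert len(planes) == len(COOCCURRENCE_NAMES)
    return planes


# ---------------------------------------------------------------------------
# reference (oracle) GLCM path, used for validation at single pixels


def window_glcm(
    plane: np.ndarray, center: tuple[int, int], window: int = 9, offsets=DEFAULT_OFFSETS
) -> np.ndarray:
    """Dense symmetric normalized 256x256 GLCM of one pixel's window.

    Independent reference implementation of the window/pair convention
    used by :func:`cooccurrence_images`.
    """
    p = np.asarray(plane)
    if p.dtype.kind == "f":
        p = np.rint(p)
    p = np.clip(p, 0, 255).astype(int)
    h, w = p.shape
    hw = window // 2
    r, c = center
    glcm = np.zeros((N_LEVELS, N_LEVELS), dtype=float)
    for rr in range(max(0, r - hw), min(h, r + hw + 1)):
        for cc in range(max(0, c - hw), min(w, c + hw + 1)):
            for dr, dc in offsets:
                r2, c2 = rr + dr, cc + dc
                if 0 <= r2 < h and 0 <= c2 < w:
                    a, b = p[rr, cc], p[r2, c2]
                    glcm[a, b] += 1.0
                    glcm[b, a] += 1.0
    total = glcm.sum()
    if total > 0:
        glcm /= total
    return glcm


def glcm_stats_reference(glcm: np.ndarray) -> dict[str, float]:
    """All 21 statistics evaluated directly on a dense normalized GLCM."""
    p = np.asarray(glcm, dtype=float)
    n = p.shape[0]
    i = np.arange(n, dtype=float)[:, None] * np.ones(n)[None, :]
    j = i.T
    px = p.sum(axis=1)
    mu_x = float(np.sum(i * p))
    var_x = float(np.sum((i - mu_x) ** 2 * p))

    def ent(q):
        q = q[q > 0]
        return float(-np.sum(q * np.log(q)))

    s = i + j
    d = np.abs(i - j)
    k_s = np.arange(2 * n - 1, dtype=float)
    p_s = np.array([p[(s == k)].sum() for k in k_s])
    k_d = np.arange(n, dtype=float)
    p_d = np.array([p[(d == k)].sum() for k in k_d])
    sum_avg = float(np.sum(k_s * p_s))
    hx = ent(px)
    hxy = ent(p)
    out = {
        "autocorrelation": float(np.sum(i * j * p)),
        "contrast": float(np.sum((i - j) ** 2 * p)),
        "correlation": (
            float(np.sum(i * j * p) - mu_x * mu_x) / var_x if var_x > 1e-12 else 0.0
        ),
        "cluster_prominence": float(np.sum((i + j - 2 * mu_x) ** 4 * p)),
        "cluster_shade": float(np.sum((i + j - 2 * mu_x) ** 3 * p)),
        "dissimilarity": float(np.sum(d * p)),
        "energy": float(np.sum(p * p)),
        "entropy": hxy,
        "homogeneity": float(np.sum(p / (1.0 + (i - j) ** 2))),
        "maximum_probability": float(p.max()),
        "variance": var_x,
        "sum_average": sum_avg,
        "sum_variance": float(np.sum((k_s - sum_avg) ** 2 * p_s)),
        "sum_entropy": ent(p_s),
        "difference_variance": float(
            np.sum(k_d**2 * p_d) - np.sum(k_d * p_d) ** 2
        ),
        "difference_entropy": ent(p_d),
        "imc1": (hxy - 2 * hx) / hx if hx > 1e-12 else 0.0,
        "imc2": float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (2 * hx - hxy))))),
        "inverse_difference": float(np.sum(p / (1.0 + d))),
        "inverse_difference_normalized": float(np.sum(p / (1.0 + d / n))),
        "inverse_difference_moment_normalized": float(
            np.sum(p / (1.0 + (i - j) ** 2 / (n * n)))
        ),
    }
    return out


# ---------------------------------------------------------------------------
# Gabor bank


@dataclass(frozen=True)
class GaborParams:
    """One Gabor filter: Gaussian envelope modulated by a sinusoid.

    ``kappa`` is the frequency shift in cycles across the kernel width;
    ``theta`` the orientation phase; ``sigma_x``/``sigma_y`` the envelope
    stds in pixels.  ``printed_rotation`` keeps the published coordinate
    transform ``y' = y cos(theta) + x sin(theta)`` (an improper rotation);
    set it False for the conventional ``y' = y cos(theta) - x sin(theta)``.
    """

    kappa: float
    theta: float
    sigma_x: float = 4.0
    sigma_y: float = 4.0
    half_width: int = 8
    printed_rotation: bool = True

    def __post_init__(self) -> None:
        if self.kappa <= 0 or self.sigma_x <= 0 or self.sigma_y <= 0:
            raise ConfigurationError("kappa and sigmas must be positive")


def gabor_kernel(params: GaborParams) -> np.ndarray:
    """Complex kernel on a (2*half_width+1)^2 grid; centre value is 1+0j."""
    hw = params.half_width
    width = 2 * hw + 1
    y, x = np.mgrid[-hw : hw + 1, -hw : hw + 1].astype(float)
    ct, st = np.cos(params.theta), np.sin(params.theta)
    xp = x * ct + y * st
    if params.printed_rotation:
        yp = y * ct + x * st
    else:
        yp = y * ct - x * st
    envelope = np.exp(-0.5 * ((xp / params.sigma_x) ** 2 + (yp / params.sigma_y) ** 2))
    phase = 2.0 * np.pi * params.kappa * xp / width
    return envelope * (np.cos(phase) + 1j * np.sin(phase))


def default_gabor_bank(half_width: int = 8, printed_rotation: bool = True):
    """kappa in {5, 9} x theta in {0, pi/6, ..., 5 pi/6}: 12 filters."""
    sigma = half_width / 2.0
    return [
        GaborParams(
            kappa=k,
            theta=e * np.pi / 6.0,
            sigma_x=sigma,
            sigma_y=sigma,
            half_width=half_width,
            printed_rotation=printed_rotation,
        )
        for k in (5.0, 9.0)
        for e in range(6)
    ]


def gabor_images(plane: np.ndarray, bank=None) -> list[np.ndarray]:
    """Real and imaginary response planes per filter (2 x len(bank)).

    Kernels are applied as correlation templates with reflected-boundary
    padding; the real part is zero-mean adjusted so flat regions give no
    response.
    """
    if bank is None:
        bank = default_gabor_bank()
    if len(bank) == 0:
        raise ConfigurationError("gabor bank must be non-empty")
    f = np.asarray(plane, dtype=float)
    out: list[np.ndarray] = []
    for params in bank:
        kern = gabor_kernel(params)
        kern = kern - kern.real.mean()  # zero-mean real part
        hw = params.half_width
        padded = np.pad(f, hw, mode="reflect")
        # correlation: flip the kernel, then convolve
        resp = fftconvolve(padded, np.conj(kern[::-1, ::-1]), mode="same")
        resp = resp[hw:-hw, hw:-hw]
        out.append(resp.real)
        out.append(resp.imag)
    return out


# ---------------------------------------------------------------------------
# aggregation and assembly


def aggregate_plane(plane: np.ndarray) -> tuple[float, float, float]:
    """(mean, population std, mode) of a feature image.

    The mode is the centre of the most populated of 256 equal-width bins
    spanning [min, max]; ties resolve to the lowest bin; a constant plane
    has mode equal to its value.
    """
    f = np.asarray(plane, dtype=float).ravel()
    if f.size == 0:
        raise ConfigurationError("empty feature plane")
    lo, hi = float(f.min()), float(f.max())
    if lo == hi:
        return lo, 0.0, lo
    counts, edges = np.histogram(f, bins=256, range=(lo, hi))
    b = int(np.argmax(counts))  # argmax takes the first (lowest) bin on ties
    mode = 0.5 * (edges[b] + edges[b + 1])
    return float(f.mean()), float(f.std()), mode


def _gabor_plane_names(bank) -> list[str]:
    names = []
    for params in bank:
        tag = f"k{params.kappa:g}_t{params.theta / np.pi * 6:.0f}pi6"
        names.append(f"{tag}_real")
        names.append(f"{tag}_imag")
    return names


def texture_feature_names(bank=None) -> tuple[str, ...]:
    if bank is None:
        bank = default_gabor_bank()
    names: list[str] = []
    stats = ("mean", "std", "mode")
    for ch in CHANNEL_NAMES:
        for feat in FIRST_ORDER_NAMES:
            names += [f"fo_{ch}_{feat}_{s}" for s in stats]
    for ch in CHANNEL_NAMES:
        for feat in COOCCURRENCE_NAMES:
            names += [f"cooc_{ch}_{feat}_{s}" for s in stats]
    for ch in CHANNEL_NAMES:
        for feat in _gabor_plane_names(bank):
            names += [f"gabor_{ch}_{feat}_{s}" for s in stats]
    return tuple(names)


TEXTURE_FEATURE_NAMES: tuple[str, ...] = texture_feature_names()
assert len(TEXTURE_FEATURE_NAMES) == 540


def texture_vector(
    image: np.ndarray,
    fo_window: int = 3,
    cooc_window: int = 9,
    offsets=DEFAULT_OFFSETS,
    bank=None,
) -> np.ndarray:
    """All 540 texture features: blocks of 135 first-order, 189
    co-occurrence and 216 Gabor aggregates, channel-major within blocks."""
    channels = to_hsi(image).planes()
    if bank is None:
        bank = default_gabor_bank()

    def agg(planes):
        vals = []
        for pl in planes:
            vals += list(aggregate_plane(pl))
        return vals

    fo = []
    for ch in channels:
        fo += agg(first_order_images(ch, fo_window))
    cooc = []
    for ch in channels:
        cooc += agg(cooccurrence_images(ch, cooc_window, offsets))
    gab = []
    for ch in channels:
        gab += agg(gabor_images(ch, bank))
    vec = np.array(fo + cooc + gab)
    assert len(fo) == 135 and len(cooc) == 189 and len(gab) == 216
    assert vec.shape == (540,)
    return vec
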