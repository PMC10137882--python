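"""Independent oracle implementations used only by the test suite.

Everything here is deliberately written from the definitions with plain
loops (or an independently structured computation), sharing no code
with the package, so agreement between the two routes is evidence and
not tautology.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


class ScriptedRng:
    """Stand-in generator that replays prescribed draws, for unit tests
    that pin specific random values (r1 = 0, chosen clue index, ...)."""

    def __init__(self, integers=(), uniforms=()):
        self._integers = list(integers)
        self._uniforms = list(uniforms)

    def integers(self, *args, **kwargs):
        return self._integers.pop(0)

    def uniform(self, low=0.0, high=1.0, size=None):
        v = self._uniforms.pop(0)
        if size is None:
            return float(v)
        v = np.asarray(v, dtype=float)
        if v.ndim == 0:
            return np.full(size, float(v))
        return v


def otsu_direct(p: np.ndarray, thresholds) -> float:
    """Between-class variance by per-class loops (no cumsums)."""
    cuts = [0, *[int(t) for t in thresholds], 256]
    mu_t = math.fsum(k * p[k] for k in range(256))
    total = 0.0
    for c in range(len(cuts) - 1):
        lo, hi = cuts[c], cuts[c + 1]
        omega = math.fsum(p[k] for k in range(lo, hi))
        if omega == 0.0:
            continue
        mu = math.fsum(k * p[k] for k in range(lo, hi)) / omega
        total += omega * (mu - mu_t) ** 2
    return total


def brute_force_otsu(p: np.ndarray, n_thresholds: int):
    """Exhaustive argmax of ``otsu_direct`` over all threshold tuples."""
    best_v, best_th = -np.inf, None
    for combo in itertools.combinations(range(1, 255), n_thresholds):
        v = otsu_direct(p, combo)
        if v > best_v:
            best_v, best_th = v, combo
    return np.array(best_th), best_v


def otsu_direct_slices(p: np.ndarray, thresholds) -> float:
    """Between-class variance via per-class slice sums (no cumsums);
    faster than ``otsu_direct`` for exhaustive pair enumeration while
    staying an independent summation route."""
    levels = np.arange(256, dtype=float)
    cuts = [0, *[int(t) for t in thresholds], 256]
    mu_t = float(np.dot(levels, p))
    total = 0.0
    for c in range(len(cuts) - 1):
        sl = slice(cuts[c], cuts[c + 1])
        omega = float(np.sum(p[sl]))
        if omega == 0.0:
            continue
        mu = float(np.dot(levels[sl], p[sl])) / omega
        total += omega * (mu - mu_t) ** 2
    return total


def brute_force_otsu_pairs(p: np.ndarray):
    """First-improvement exhaustive scan over all threshold pairs."""
    best_v, best_th = -np.inf, None
    for t1 in range(1, 254):
        for t2 in range(t1 + 1, 255):
            v = otsu_direct_slices(p, (t1, t2))
            if v > best_v:
                best_v, best_th = v, (t1, t2)
    return np.array(best_th), best_v


def within_class_variance(p: np.ndarray, thresholds) -> float:
    cuts = [0, *[int(t) for t in thresholds], 256]
    total = 0.0
    for c in range(len(cuts) - 1):
        lo, hi = cuts[c], cuts[c + 1]
        omega = math.fsum(p[k] for k in range(lo, hi))
        if omega == 0.0:
            continue
        mu = math.fsum(k * p[k] for k in range(lo, hi)) / omega
        total += math.fsum(p[k] * (k - mu) ** 2 for k in range(lo, hi))
    return total


def histogram_variance(p: np.ndarray) -> float:
    mu = math.fsum(k * p[k] for k in range(256))
    return math.fsum(p[k] * (k - mu) ** 2 for k in range(256))


def smooth_step_direct(k: float, q: float, u: float, v: float) -> float:
    if k <= q:
        return 0.0
    if k <= u:
        return (k - q) ** 2 / ((v - q) * (u - q))
    if k <= v:
        return 1.0 - (k - v) ** 2 / ((v - q) * (v - u))
    return 1.0


def fuzzy_memberships_direct(k: float, triplets: np.ndarray) -> list[float]:
    n = triplets.shape[0]
    steps = [smooth_step_direct(k, *triplets[i]) for i in range(n)]
    out = [1.0 - steps[0]]
    for r in range(1, n):
        out.append(steps[r - 1] - steps[r])
    out.append(steps[n - 1])
    return out


def fuzzy_entropy_direct(p: np.ndarray, triplets: np.ndarray) -> float:
    """Fuzzy-region Shannon entropy by direct summation over k = 0..255."""
    n_regions = triplets.shape[0] + 1
    total = 0.0
    for r in range(n_regions):
        pr = math.fsum(
            p[k] * fuzzy_memberships_direct(float(k), triplets)[r]
            for k in range(256)
        )
        if pr <= 0.0:
            continue
        for k in range(256):
            w = p[k] * fuzzy_memberships_direct(float(k), triplets)[r] / pr
            if w > 0.0:
                total -= w * math.log(w)
    return total


# --------------------------------------------------------------- FSIM oracle
def _log_gabor_shifted(shape, scale, orient, n_orient=4,
                       min_wavelength=6.0, mult=2.0, sigma_onf=0.55,
                       d_theta_on_sigma=1.2) -> np.ndarray:
    """Same filter definition, independently constructed on a
    fftshift-centred grid and shifted back."""
    rows, cols = shape
    y = (np.arange(rows) - rows // 2) / rows
    x = (np.arange(cols) - cols // 2) / cols
    xx, yy = np.meshgrid(x, y)
    radius = np.hypot(xx, yy)
    centre = (rows // 2, cols // 2)
    radius[centre] = 1.0
    theta = np.arctan2(-yy, xx)

    f0 = 1.0 / (min_wavelength * mult**scale)
    radial = np.exp(-(np.log(radius / f0) ** 2) / (2.0 * np.log(sigma_onf) ** 2))
    radial[centre] = 0.0

    angle = orient * np.pi / n_orient
    ds = np.sin(theta) * np.cos(angle) - np.cos(theta) * np.sin(angle)
    dc = np.cos(theta) * np.cos(angle) + np.sin(theta) * np.sin(angle)
    dtheta = np.abs(np.arctan2(ds, dc))
    theta_sigma = (np.pi / n_orient) / d_theta_on_sigma
    spread = np.exp(-(dtheta**2) / (2.0 * theta_sigma**2))
    return np.fft.ifftshift(radial * spread)


def phase_congruency_reference(img: np.ndarray, n_scales=4, n_orient=4,
                               epsilon=1e-4) -> np.ndarray:
    spectrum = np.fft.fft2(img.astype(float))
    energy = np.zeros(img.shape)
    amplitude = np.zeros(img.shape)
    for o in range(n_orient):
        acc = np.zeros(img.shape, dtype=complex)
        for s in range(n_scales):
            filt = _log_gabor_shifted(img.shape, s, o, n_orient)
            resp = np.fft.ifft2(spectrum * filt)
            acc += resp
            amplitude += np.abs(resp)
        energy += np.abs(acc)
    return energy / (epsilon + amplitude)


def fsim_reference(a: np.ndarray, b: np.ndarray) -> float:
    from scipy.signal import convolve2d

    def lum(img):
        img = np.asarray(img, dtype=float)
        if img.ndim == 3:
            return 0.299 * img[..., 0] + 0.587 * img[..., 1] + 0.114 * img[..., 2]
        return img

    def grad(img):
        kx = np.array([[3., 0., -3.], [10., 0., -10.], [3., 0., -3.]]) / 16.0
        gx = convolve2d(img, kx, mode="same", boundary="symm")
        gy = convolve2d(img, kx.T, mode="same", boundary="symm")
        return np.hypot(gx, gy)

    a, b = lum(a), lum(b)
    pc1, pc2 = phase_congruency_reference(a), phase_congruency_reference(b)
    g1, g2 = grad(a), grad(b)
    t1, t2 = 0.85, 160.0
    s_pc = (2 * pc1 * pc2 + t1) / (pc1**2 + pc2**2 + t1)
    s_g = (2 * g1 * g2 + t2) / (g1**2 + g2**2 + t2)
    pcm = np.maximum(pc1, pc2)
    return float((s_pc * s_g * pcm).sum() / pcm.sum())
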