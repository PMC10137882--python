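"""Segmentation fidelity metrics: RMSE/PSNR, SSIM, FSIM, and the STD
summary used in result tables.

PSNR is ``20 log10(255 / RMSE)`` with the RMSE taken over all pixels
and channels jointly.  SSIM uses whole-image (global) statistics with
the usual stabilizers ``c_a = (0.01*255)^2`` and ``c_b = (0.03*255)^2``;
a sliding-window variant is available behind a flag.  FSIM weights the
pointwise similarity of two feature maps — phase congruency (computed
from a log-Gabor filter bank, 4 scales x 4 orientations, as the ratio
of local energy to total local amplitude) and gradient magnitude
(Scharr) — by the elementwise maximum of the two phase-congruency maps;
RGB inputs are reduced to luminance (ITU-R 601 weights) first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.metrics import structural_similarity as _skimage_ssim

__all__ = ["MetricsReport", "psnr", "rmse", "ssim", "fsim", "run_std",
           "phase_congruency", "metrics_report"]

_C_A = (0.01 * 255.0) ** 2
_C_B = (0.03 * 255.0) ** 2
_FSIM_T1 = 0.85   # phase-congruency similarity stabilizer
_FSIM_T2 = 160.0  # gradient-magnitude similarity stabilizer


@dataclass(frozen=True)
class MetricsReport:
    psnr_db: float  # may be +inf
    psnr_infinite: bool
    ssim: float
    fsim: float
    rmse: float

    def to_dict(self) -> dict:
        return {
            "psnr_db": None if self.psnr_infinite else float(self.psnr_db),
            "psnr_infinite": self.psnr_infinite,
            "ssim": float(self.ssim),
            "fsim": float(self.fsim),
            "rmse": float(self.rmse),
        }


def _check_pair(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"image shapes differ: {a.shape} vs {b.shape}")
    return a, b


def rmse(original, segmented) -> float:
    a, b = _check_pair(original, segmented)
    return float(np.sqrt(np.mean((a - b) ** 2)))


def psnr(original, segmented) -> float:
    """Peak signal-to-noise ratio in dB; +inf for identical images."""
    r = rmse(original, segmented)
    if r == 0.0:
        return float("inf")
    return float(20.0 * np.log10(255.0 / r))


def _ssim_global(a: np.ndarray, b: np.ndarray) -> float:
    mu1, mu2 = a.mean(), b.mean()
    var1, var2 = a.var(), b.var()
    cov = np.mean((a - mu1) * (b - mu2))
    return float(
        (2 * mu1 * mu2 + _C_A) * (2 * cov + _C_B)
        / ((mu1**2 + mu2**2 + _C_A) * (var1 + var2 + _C_B))
    )


def ssim(original, segmented, windowed: bool = False) -> float:
    """Structural similarity; global statistics by default, channels
    averaged for RGB.  ``windowed=True`` uses the sliding-window form."""
    a, b = _check_pair(original, segmented)
    if windowed:
        return float(
            _skimage_ssim(
                a, b, data_range=255.0,
                channel_axis=-1 if a.ndim == 3 else None,
            )
        )
    if a.ndim == 3:
        return float(np.mean([_ssim_global(a[..., c], b[..., c])
                              for c in range(a.shape[2])]))
    return _ssim_global(a, b)


def _luminance(img: np.ndarray) -> np.ndarray:
    if img.ndim == 3:
        w = np.array([0.299, 0.587, 0.114])
        return img[..., :3] @ w
    return img


def _log_gabor_bank(
    shape: tuple[int, int],
    n_scales: int = 4,
    n_orient: int = 4,
    min_wavelength: float = 6.0,
    mult: float = 2.0,
    sigma_onf: float = 0.55,
    d_theta_on_sigma: float = 1.2,
) -> list[list[np.ndarray]]:
    """Frequency-domain log-Gabor filters, [orientation][scale]."""
    rows, cols = shape
    fy = np.fft.fftfreq(rows)[:, None]
    fx = np.fft.fftfreq(cols)[None, :]
    radius = np.sqrt(fx**2 + fy**2)
    radius[0, 0] = 1.0  # avoid log(0); the DC entry is zeroed below
    theta = np.arctan2(-fy, fx)
    sin_t, cos_t = np.sin(theta), np.cos(theta)
    theta_sigma = (np.pi / n_orient) / d_theta_on_sigma

    bank: list[list[np.ndarray]] = []
    log_sigma2 = 2.0 * np.log(sigma_onf) ** 2
    for o in range(n_orient):
        angle = o * np.pi / n_orient
        ds = sin_t * np.cos(angle) - cos_t * np.sin(angle)
        dc = cos_t * np.cos(angle) + sin_t * np.sin(angle)
        dtheta = np.abs(np.arctan2(ds, dc))
        spread = np.exp(-(dtheta**2) / (2 * theta_sigma**2))
        filters = []
        for s in range(n_scales):
            wavelength = min_wavelength * mult**s
            f0 = 1.0 / wavelength
            log_rad = np.log(radius / f0)
            radial = np.exp(-(log_rad**2) / log_sigma2)
            radial[0, 0] = 0.0
            filters.append(radial * spread)
        bank.append(filters)
    return bank


def phase_congruency(
    img: np.ndarray,
    n_scales: int = 4,
    n_orient: int = 4,
    epsilon: float = 1e-4,
    **bank_kwargs,
) -> np.ndarray:
    """Phase-congruency map PC = sum_o E_o / (eps + sum_o sum_n A_no).

    E_o is the magnitude of the summed complex (even + i*odd) filter
    responses over scales for orientation o and A_no the per-scale
    response amplitudes — local energy over total local amplitude, 1
    where all scales agree in phase, near 0 in featureless regions.
    """
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise ValueError("phase congruency expects a single channel")
    if min(img.shape) < 16:
        raise ValueError("image smaller than the filter support (min side 16)")
    spectrum = np.fft.fft2(img)
    bank = _log_gabor_bank(img.shape, n_scales, n_orient, **bank_kwargs)
    energy = np.zeros(img.shape)
    amplitude = np.zeros(img.shape)
    for filters in bank:
        sum_response = np.zeros(img.shape, dtype=complex)
        for filt in filters:
            response = np.fft.ifft2(spectrum * filt)
            amplitude += np.abs(response)
            sum_response += response
        energy += np.abs(sum_response)
    return energy / (epsilon + amplitude)


def _scharr_gradient(img: np.ndarray) -> np.ndarray:
    kx = np.array([[3.0, 0.0, -3.0], [10.0, 0.0, -10.0], [3.0, 0.0, -3.0]]) / 16.0
    ky = kx.T
    from scipy.ndimage import convolve

    gx = convolve(img, kx, mode="nearest")
    gy = convolve(img, ky, mode="nearest")
    return np.sqrt(gx**2 + gy**2)


def fsim(original, segmented) -> float:
    """Feature similarity index in [0, 1]; 1 for identical images."""
    a, b = _check_pair(original, segmented)
    a, b = _luminance(a), _luminance(b)
    pc1 = phase_congruency(a)
    pc2 = phase_congruency(b)
    g1 = _scharr_gradient(a)
    g2 = _scharr_gradient(b)
    s_pc = (2 * pc1 * pc2 + _FSIM_T1) / (pc1**2 + pc2**2 + _FSIM_T1)
    s_g = (2 * g1 * g2 + _FSIM_T2) / (g1**2 + g2**2 + _FSIM_T2)
    pc_max = np.maximum(pc1, pc2)
    weight = float(np.sum(pc_max))
    if weight == 0.0:  # featureless (constant) images: unweighted mean
        return float(np.mean(s_pc * s_g))
    return float(np.sum(s_pc * s_g * pc_max) / weight)


def run_std(values) -> float:
    """Population standard deviation sqrt(mean((x - mean)^2)) of a
    vector of per-run results."""
    v = np.asarray(values, dtype=float).reshape(-1)
    if v.size == 0:
        raise ValueError("run_std needs a nonempty vector")
    return float(np.sqrt(np.mean((v - v.mean()) ** 2)))


def metrics_report(original, segmented) -> MetricsReport:
    r = rmse(original, segmented)
    p = psnr(original, segmented)
    return MetricsReport(
        psnr_db=p,
        psnr_infinite=not np.isfinite(p),
        ssim=ssim(original, segmented),
        fsim=fsim(original, segmented),
        rmse=r,
    )
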