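"""Histogram construction and the two thresholding objectives.

Multi-level thresholding picks nTh cut points in the 8-bit gray range
that partition a channel's 256-bin normalized histogram into nTh + 1
classes.  Two criteria are implemented:

* **Otsu between-class variance** — maximize
  ``sum_j omega_j * (mu_j - mu_T)**2`` where ``omega_j`` and ``mu_j``
  are the probability mass and mean gray level of class j and ``mu_T``
  is the global mean.  Empty classes contribute zero.

* **Fuzzy entropy** — gray levels belong *partially* to nTh + 1 regions
  through piecewise-quadratic membership functions parameterized by
  ordered triplets (q_i, u_i, v_i).  Region 0 is Z-shaped (dark), the
  last region S-shaped (bright), interior regions are Pi-shaped by
  composing the rising head of one triplet with the falling tail of the
  next; the memberships sum to one at every level by construction.  The
  objective is the summed Shannon entropy of the fuzzy-region
  distributions, maximized when the regions split the histogram into
  maximally even, well-separated masses.  A crisp threshold is recovered
  from each triplet as the gray level where the region membership
  crosses one half.

Optimizer agents are real vectors in [0, 255]^D; ``decode_agent`` maps
them to valid ``ThresholdSet``/``FuzzyParams`` objects.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
import pandas as pd

__all__ = [
    "Histogram",
    "ThresholdSet",
    "FuzzyParams",
    "OtsuStats",
    "normalized_histogram",
    "otsu_objective",
    "otsu_stats",
    "fuzzy_memberships",
    "fuzzy_thresholds",
    "fuzzy_entropy_objective",
    "decode_agent",
    "exhaustive_otsu",
]

_LEVELS = np.arange(256, dtype=float)


@dataclass(frozen=True)
class Histogram:
    """256-bin normalized gray-level histogram of one channel."""

    p: np.ndarray
    n_pixels: int

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        if p.shape != (256,):
            raise ValueError("histogram must have exactly 256 bins")
        if np.any(p < 0):
            raise ValueError("histogram probabilities must be nonnegative")
        if abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("histogram probabilities must sum to 1")
        object.__setattr__(self, "p", p)

    def to_csv(self, path) -> None:
        pd.DataFrame({"level": np.arange(256), "probability": self.p}).to_csv(
            path, index=False
        )

    @staticmethod
    def from_csv(path) -> "Histogram":
        df = pd.read_csv(path)
        p = np.zeros(256)
        p[df["level"].to_numpy(dtype=int)] = df["probability"].to_numpy(dtype=float)
        return Histogram(p=p / p.sum(), n_pixels=max(int(round(p.sum())), 1))


@dataclass(frozen=True)
class ThresholdSet:
    """Strictly increasing integer thresholds, each in [1, 254]."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=int)
        if v.ndim != 1 or v.size == 0:
            raise ValueError("need at least one threshold")
        if np.any(v < 1) or np.any(v > 254):
            raise ValueError("thresholds must lie in [1, 254]")
        if np.any(np.diff(v) <= 0):
            raise ValueError("thresholds must be strictly increasing")
        object.__setattr__(self, "values", v)

    @property
    def n_thresholds(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class FuzzyParams:
    """nTh ordered (q, u, v) triplets forming one global strict chain
    0 <= q1 < u1 < v1 < q2 < ... <= 255."""

    triplets: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.triplets, dtype=float)
        if t.ndim != 2 or t.shape[1] != 3 or t.shape[0] < 1:
            raise ValueError("triplets must be an (nTh, 3) array")
        flat = t.reshape(-1)
        if flat[0] < 0 or flat[-1] > 255:
            raise ValueError("fuzzy parameters must lie in [0, 255]")
        if np.any(np.diff(flat) <= 0):
            raise ValueError("fuzzy parameters must form a strictly increasing chain")
        object.__setattr__(self, "triplets", t)

    @property
    def n_thresholds(self) -> int:
        return self.triplets.shape[0]


@dataclass(frozen=True)
class OtsuStats:
    omegas: np.ndarray
    mus: np.ndarray
    mu_total: float


def normalized_histogram(channel: np.ndarray) -> Histogram:
    """Normalized 256-bin histogram of an 8-bit channel."""
    arr = np.asarray(channel)
    if arr.size == 0:
        raise ValueError("channel must be nonempty")
    flat = arr.reshape(-1)
    if np.any(flat < 0) or np.any(flat > 255):
        raise ValueError("pixel values must lie in [0, 255]")
    counts = np.bincount(flat.astype(np.int64), minlength=256).astype(float)
    return Histogram(p=counts / flat.size, n_pixels=int(flat.size))


def _class_edges(th: np.ndarray) -> list[tuple[int, int]]:
    """Half-open class intervals [lo, hi] (inclusive) induced by thresholds:
    class c holds gray levels g with (number of thresholds <= g) == c."""
    cuts = [0, *[int(t) for t in th], 256]
    return [(cuts[i], cuts[i + 1] - 1) for i in range(len(cuts) - 1)]


def otsu_stats(hist: Histogram, th: ThresholdSet) -> OtsuStats:
    """Class masses and means for the partition induced by ``th``."""
    p = hist.p
    cp = np.concatenate([[0.0], np.cumsum(p)])
    cm = np.concatenate([[0.0], np.cumsum(p * _LEVELS)])
    edges = np.array([0, *th.values.tolist(), 256])
    omegas = cp[edges[1:]] - cp[edges[:-1]]
    masses = cm[edges[1:]] - cm[edges[:-1]]
    mu_total = float(cm[-1])
    with np.errstate(invalid="ignore", divide="ignore"):
        mus = np.where(omegas > 0, masses / np.where(omegas > 0, omegas, 1.0), 0.0)
    return OtsuStats(omegas=omegas, mus=mus, mu_total=mu_total)


def otsu_objective(hist: Histogram, th: ThresholdSet) -> float:
    """Between-class variance sum_j omega_j (mu_j - mu_T)^2; empty classes
    contribute zero."""
    st = otsu_stats(hist, th)
    return float(np.sum(st.omegas * (st.mus - st.mu_total) ** 2))


def exhaustive_otsu(
    hist: Histogram, n_thresholds: int, return_ties: bool = False
) -> tuple[ThresholdSet, float] | tuple[ThresholdSet, float, np.ndarray]:
    """Global optimum of the Otsu criterion by exhaustive enumeration.

    Vectorized for 1 and 2 thresholds (the sizes used as oracles);
    falls back to itertools enumeration above that.

    When the histogram has empty stretches the optimum is a *plateau*:
    moving a threshold across unoccupied bins leaves every class — and
    hence the objective — bitwise unchanged.  With ``return_ties=True``
    the full argmax set (exact float ties) is returned as a third
    element, one threshold vector per row.
    """
    p = hist.p
    cp = np.concatenate([[0.0], np.cumsum(p)])
    cm = np.concatenate([[0.0], np.cumsum(p * _LEVELS)])
    mu_t = cm[-1]

    def var_from_edges(edges: np.ndarray) -> np.ndarray:
        # edges: (..., k+2) cut positions 0 .. 256
        om = cp[edges[..., 1:]] - cp[edges[..., :-1]]
        ms = cm[edges[..., 1:]] - cm[edges[..., :-1]]
        with np.errstate(invalid="ignore", divide="ignore"):
            mu = np.where(om > 0, ms / np.where(om > 0, om, 1.0), 0.0)
        return np.sum(om * (mu - mu_t) ** 2, axis=-1)

    if n_thresholds == 1:
        t = np.arange(1, 255)
        edges = np.stack([np.zeros_like(t), t, np.full_like(t, 256)], axis=-1)
        v = var_from_edges(edges)
        candidates = t[:, None]
    elif n_thresholds == 2:
        t1, t2 = np.meshgrid(np.arange(1, 255), np.arange(1, 255), indexing="ij")
        keep = t1 < t2
        t1, t2 = t1[keep], t2[keep]
        edges = np.stack(
            [np.zeros_like(t1), t1, t2, np.full_like(t1, 256)], axis=-1
        )
        v = var_from_edges(edges)
        candidates = np.stack([t1, t2], axis=-1)
    else:
        combos = np.array(
            list(itertools.combinations(range(1, 255), n_thresholds)), dtype=int
        )
        v = np.array(
            [otsu_objective(hist, ThresholdSet(values=c)) for c in combos]
        )
        candidates = combos

    i = int(np.argmax(v))
    best = ThresholdSet(values=candidates[i]), float(v[i])
    if not return_ties:
        return best
    ties = candidates[v == v[i]]
    return best[0], best[1], ties


def _smooth_step(k: np.ndarray, q: float, u: float, v: float) -> np.ndarray:
    """Piecewise-quadratic S-shaped ramp: 0 below q, 1 above v, the two
    quadratic arcs meeting continuously at u."""
    k = np.asarray(k, dtype=float)
    out = np.zeros_like(k)
    rising = (k >= q) & (k <= u)
    falling = (k > u) & (k <= v)
    denom_r = (v - q) * (u - q)
    denom_f = (v - q) * (v - u)
    if denom_r > 0:
        out[rising] = (k[rising] - q) ** 2 / denom_r
    else:
        out[rising] = 1.0
    if denom_f > 0:
        out[falling] = 1.0 - (k[falling] - v) ** 2 / denom_f
    else:
        out[falling] = 1.0
    out[k > v] = 1.0
    return out


def fuzzy_memberships(k, params: FuzzyParams) -> np.ndarray:
    """Membership of gray level(s) ``k`` in each of the nTh + 1 regions.

    Returns shape (len(k), nTh + 1) for array input, (nTh + 1,) for a
    scalar.  Region r is the difference of consecutive S-ramps, so the
    rows sum to one exactly (telescoping).
    """
    scalar = np.isscalar(k)
    karr = np.atleast_1d(np.asarray(k, dtype=float))
    if np.any(karr < 0) or np.any(karr > 255):
        raise ValueError("gray levels must lie in [0, 255]")
    n = params.n_thresholds
    # steps[i] = S-ramp of triplet i; region 0 = 1 - steps[0],
    # region r = steps[r-1] - steps[r], region n = steps[n-1].
    steps = np.stack(
        [_smooth_step(karr, *params.triplets[i]) for i in range(n)], axis=-1
    )
    ones = np.ones_like(karr)
    zeros = np.zeros_like(karr)
    padded = np.concatenate([ones[..., None], steps, zeros[..., None]], axis=-1)
    memberships = padded[..., :-1] - padded[..., 1:]
    memberships = np.clip(memberships, 0.0, 1.0)
    return memberships[0] if scalar else memberships


def fuzzy_thresholds(params: FuzzyParams) -> ThresholdSet:
    """Crisp thresholds: the gray level where each triplet's S-ramp
    crosses one half (closed form), rounded and strictly ordered."""
    raw = []
    for q, u, v in params.triplets:
        if (q + v) / 2.0 <= u:
            t = q + np.sqrt((v - q) * (u - q) / 2.0)
        else:
            t = v - np.sqrt((v - q) * (v - u) / 2.0)
        raw.append(t)
    vals = np.clip(np.round(np.asarray(raw)), 1, 254).astype(int)
    return ThresholdSet(values=_enforce_strict(vals))


def _fuzzy_region_probs(hist: Histogram, params: FuzzyParams) -> tuple[np.ndarray, np.ndarray]:
    mem = fuzzy_memberships(_LEVELS, params)  # (256, n+1)
    weighted = hist.p[:, None] * mem
    return weighted, weighted.sum(axis=0)


def fuzzy_entropy_objective(hist: Histogram, params: FuzzyParams) -> float:
    """Summed Shannon entropy of the fuzzy-region distributions.

    H = sum_r -sum_k (p_k mu_r(k) / P_r) ln(p_k mu_r(k) / P_r) with
    P_r = sum_k p_k mu_r(k); 0 ln 0 := 0 and regions of zero mass
    contribute zero.  Natural log.
    """
    weighted, p_regions = _fuzzy_region_probs(hist, params)
    total = 0.0
    for r in range(weighted.shape[1]):
        pr = p_regions[r]
        if pr <= 0:
            continue
        w = weighted[:, r] / pr
        w = w[w > 0]
        total -= float(np.sum(w * np.log(w)))
    return total


def _enforce_strict(vals: np.ndarray, lo: int = 1, hi: int = 254) -> np.ndarray:
    """Bump duplicates upward (cascading) to restore strict order within
    [lo, hi]; a final backward pass keeps the chain under the cap."""
    v = np.sort(np.asarray(vals, dtype=int))
    n = v.size
    if n > hi - lo + 1:
        raise ValueError("too many thresholds for the gray range")
    for i in range(n):
        floor = lo + i if i == 0 else max(lo + i, v[i - 1] + 1)
        if v[i] < floor:
            v[i] = floor
    for i in range(n - 1, -1, -1):
        cap = hi - (n - 1 - i)
        if v[i] > cap:
            v[i] = cap
    return v


def decode_agent(
    x: np.ndarray, n_thresholds: int, method: Literal["otsu", "fuzzy"]
) -> ThresholdSet | FuzzyParams:
    """Map a real agent vector in [0, 255]^D to a valid parameter object.

    ``otsu``: D = nTh — sort, round, clamp to [1, 254], bump duplicates
    upward.  ``fuzzy``: D = 3 nTh — sort the whole vector ascending into
    consecutive triplets, nudging exact ties apart by one ulp.
    """
    if n_thresholds < 1 or n_thresholds >= 254:
        raise ValueError("n_thresholds must lie in [1, 253]")
    x = np.asarray(x, dtype=float)
    if method == "otsu":
        if x.size != n_thresholds:
            raise ValueError(f"expected {n_thresholds} components, got {x.size}")
        vals = _enforce_strict(np.round(np.clip(x, 1, 254)).astype(int))
        return ThresholdSet(values=vals)
    if method == "fuzzy":
        if x.size != 3 * n_thresholds:
            raise ValueError(f"expected {3 * n_thresholds} components, got {x.size}")
        chain = np.sort(np.clip(x, 0.0, 255.0))
        for i in range(1, chain.size):
            if chain[i] <= chain[i - 1]:
                chain[i] = np.nextafter(chain[i - 1], np.inf)
        if chain[-1] > 255.0:  # ulp cascade cannot realistically pass 255
            chain -= chain[-1] - 255.0
            for i in range(1, chain.size):
                if chain[i] <= chain[i - 1]:
                    chain[i] = np.nextafter(chain[i - 1], np.inf)
        return FuzzyParams(triplets=chain.reshape(n_thresholds, 3))
    raise ValueError("method must be 'otsu' or 'fuzzy'")
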