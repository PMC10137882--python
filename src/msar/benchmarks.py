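"""CEC'2020-style bound-constrained test functions with synthetic data.

The ten-function suite (one unimodal, three multimodal, three hybrid,
three composition functions, searched on [-100, 100]^D) follows the
public competition definitions for the base families, hybrid
subcomponent proportions and composition weights.  The official shift /
rotation / permutation data files are **not** bundled: shifts are drawn
uniformly in [-80, 80] and rotations are random orthogonal matrices (QR
of a Gaussian matrix), both from a user seed.  Absolute values are
therefore not comparable with published tables that used the official
data — the suite exists to exercise and compare optimizers under
controlled, reproducible conditions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = ["BenchmarkFunction", "make_suite", "evaluate", "FUNCTION_OFFSETS"]

FUNCTION_OFFSETS = {
    "F1": 100.0, "F2": 1100.0, "F3": 700.0, "F4": 1900.0, "F5": 1700.0,
    "F6": 1600.0, "F7": 2100.0, "F8": 2200.0, "F9": 2400.0, "F10": 2500.0,
}

_BOX = 100.0


# ---------------------------------------------------------------- base maps
def bent_cigar(z: np.ndarray) -> float:
    return float(z[0] ** 2 + 1e6 * np.sum(z[1:] ** 2))


def elliptic(z: np.ndarray) -> float:
    d = z.size
    if d == 1:
        return float(z[0] ** 2)
    w = 1e6 ** (np.arange(d) / (d - 1))
    return float(np.sum(w * z**2))


def discus(z: np.ndarray) -> float:
    return float(1e6 * z[0] ** 2 + np.sum(z[1:] ** 2))


def rastrigin(z: np.ndarray) -> float:
    return float(np.sum(z**2 - 10.0 * np.cos(2 * np.pi * z) + 10.0))


def griewank(z: np.ndarray) -> float:
    i = np.arange(1, z.size + 1)
    return float(np.sum(z**2) / 4000.0 - np.prod(np.cos(z / np.sqrt(i))) + 1.0)


def ackley(z: np.ndarray) -> float:
    d = z.size
    return float(
        -20.0 * np.exp(-0.2 * np.sqrt(np.sum(z**2) / d))
        - np.exp(np.sum(np.cos(2 * np.pi * z)) / d)
        + 20.0 + np.e
    )


def rosenbrock(z: np.ndarray) -> float:
    # competition convention: optimum shifted to the origin via z + 1
    y = z + 1.0
    return float(np.sum(100.0 * (y[:-1] ** 2 - y[1:]) ** 2 + (y[:-1] - 1.0) ** 2))


def modified_schwefel(z: np.ndarray) -> float:
    d = z.size
    w = z + 4.209687462275036e2
    out = np.empty(d)
    for i, wi in enumerate(w):
        if abs(wi) <= 500.0:
            out[i] = wi * np.sin(np.sqrt(abs(wi)))
        elif wi > 500.0:
            out[i] = (500.0 - wi % 500.0) * np.sin(np.sqrt(abs(500.0 - wi % 500.0))) \
                - (wi - 500.0) ** 2 / (10000.0 * d)
        else:
            out[i] = (abs(wi) % 500.0 - 500.0) * np.sin(
                np.sqrt(abs(abs(wi) % 500.0 - 500.0))
            ) - (wi + 500.0) ** 2 / (10000.0 * d)
    return float(4.189828872724338e2 * d - np.sum(out))


def hgbat(z: np.ndarray) -> float:
    y = z - 1.0  # optimum at origin of the shifted frame
    s2 = np.sum(y**2)
    s1 = np.sum(y)
    d = z.size
    return float(
        np.sqrt(abs(s2**2 - s1**2)) + (0.5 * s2 + s1) / d + 0.5
    )


def happycat(z: np.ndarray) -> float:
    y = z - 1.0
    s2 = np.sum(y**2)
    s1 = np.sum(y)
    d = z.size
    return float(abs(s2 - d) ** 0.25 + (0.5 * s2 + s1) / d + 0.5)


def _schaffer_f6(x: float, y: float) -> float:
    s = x**2 + y**2
    return 0.5 + (np.sin(np.sqrt(s)) ** 2 - 0.5) / (1.0 + 0.001 * s) ** 2


def expanded_schaffer_f6(z: np.ndarray) -> float:
    pairs = [(z[i], z[(i + 1) % z.size]) for i in range(z.size)]
    return float(sum(_schaffer_f6(a, b) for a, b in pairs))


def expanded_rosenbrock_griewank(z: np.ndarray) -> float:
    y = z + 1.0
    total = 0.0
    for i in range(z.size):
        a, b = y[i], y[(i + 1) % z.size]
        r = 100.0 * (a**2 - b) ** 2 + (a - 1.0) ** 2
        total += r**2 / 4000.0 - np.cos(r) + 1.0
    return float(total)


def lunacek_bi_rastrigin(z: np.ndarray, rotation: np.ndarray) -> float:
    """Double-funnel Rastrigin.  ``z`` is expected pre-scaled to the
    native [-5.12, 5.12]-like frame (0.1 * (x - shift) here)."""
    d = z.size
    mu0 = 2.5
    s = 1.0 - 1.0 / (2.0 * np.sqrt(d + 20.0) - 8.2)
    mu1 = -np.sqrt((mu0**2 - 1.0) / s)
    y = z + mu0  # optimum of the first funnel at z = 0
    f1 = np.sum((y - mu0) ** 2)
    f2 = 1.0 * d + s * np.sum((y - mu1) ** 2)
    zrot = rotation @ (y - mu0)
    return float(min(f1, f2) + 10.0 * (d - np.sum(np.cos(2 * np.pi * zrot))))


# ------------------------------------------------------------- construction
@dataclass(frozen=True)
class BenchmarkFunction:
    """One suite member: shifted/rotated callable with its target offset."""

    id: str
    dim: int
    shift: np.ndarray
    rotation: np.ndarray
    f_star: float
    func: Callable[[np.ndarray], float]
    manifest: dict = field(default_factory=dict)

    def __call__(self, x: np.ndarray) -> float:
        return evaluate(self, x)


def evaluate(fn: BenchmarkFunction, x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    if x.shape != (fn.dim,):
        raise ValueError(f"expected a length-{fn.dim} vector")
    if np.any(x < -_BOX) or np.any(x > _BOX):
        raise ValueError(f"input outside the search box [-{_BOX}, {_BOX}]^D")
    return float(fn.func(x))


def _random_rotation(rng: np.random.Generator, dim: int) -> np.ndarray:
    q, r = np.linalg.qr(rng.standard_normal((dim, dim)))
    return q * np.sign(np.diag(r))  # unique QR -> Haar-distributed


def _partition(dim: int, proportions: list[float], rng: np.random.Generator) -> list[np.ndarray]:
    sizes = [int(np.ceil(p * dim)) for p in proportions[:-1]]
    while sum(sizes) >= dim:  # keep at least one variable for the last chunk
        sizes[int(np.argmax(sizes))] -= 1
    sizes.append(dim - sum(sizes))
    perm = rng.permutation(dim)
    chunks, start = [], 0
    for s in sizes:
        chunks.append(perm[start:start + s])
        start += s
    return chunks


# native-domain scaling factors (search box half-width 100 -> component domain)
_HYBRID_COMPONENTS = {
    "schwefel": (modified_schwefel, 1000.0 / 100.0),
    "rastrigin": (rastrigin, 5.12 / 100.0),
    "elliptic": (elliptic, 1.0),
    "schaffer": (expanded_schaffer_f6, 1.0),
    "hgbat": (hgbat, 5.0 / 100.0),
    "rosenbrock": (rosenbrock, 2.048 / 100.0),
    "ackley": (ackley, 1.0),
    "griewank": (griewank, 600.0 / 100.0),
    "discus": (discus, 1.0),
    "happycat": (happycat, 5.0 / 100.0),
}

_HYBRID_SPECS = {
    "F5": (["schwefel", "rastrigin", "elliptic"], [0.3, 0.3, 0.4]),
    "F6": (["schaffer", "hgbat", "rosenbrock", "schwefel"], [0.2, 0.2, 0.3, 0.3]),
    "F7": (
        ["schaffer", "hgbat", "rosenbrock", "schwefel", "elliptic"],
        [0.1, 0.2, 0.2, 0.2, 0.3],
    ),
}

_COMPOSITION_SPECS = {
    "F8": (
        ["rastrigin", "griewank", "schwefel"],
        [10.0, 20.0, 30.0], [1.0, 10.0, 1.0], [0.0, 100.0, 200.0],
    ),
    "F9": (
        ["ackley", "elliptic", "griewank", "rastrigin"],
        [10.0, 20.0, 30.0, 40.0], [10.0, 1e-6, 10.0, 1.0],
        [0.0, 100.0, 200.0, 300.0],
    ),
    "F10": (
        ["rastrigin", "happycat", "ackley", "discus", "rosenbrock"],
        [10.0, 20.0, 30.0, 40.0, 50.0], [10.0, 1.0, 10.0, 1e-6, 1.0],
        [0.0, 100.0, 200.0, 300.0, 400.0],
    ),
}


def _make_basic(fid: str, dim: int, rng: np.random.Generator) -> BenchmarkFunction:
    shift = rng.uniform(-80.0, 80.0, size=dim)
    rotation = _random_rotation(rng, dim)
    f_star = FUNCTION_OFFSETS[fid]

    if fid == "F1":
        base, scale = bent_cigar, 1.0
    elif fid == "F2":
        base, scale = modified_schwefel, 1000.0 / 100.0
    elif fid == "F4":
        base, scale = expanded_rosenbrock_griewank, 2.048 / 100.0
    elif fid == "F3":
        rot2 = _random_rotation(rng, dim)

        def func(x: np.ndarray, _s=shift, _r=rot2, _o=f_star) -> float:
            return lunacek_bi_rastrigin(0.1 * (x - _s), _r) + _o

        return BenchmarkFunction(
            fid, dim, shift, rotation, f_star, func,
            manifest={"family": "lunacek_bi_rastrigin", "scale": 0.1},
        )
    else:  # pragma: no cover
        raise ValueError(fid)

    def func(x: np.ndarray, _s=shift, _r=rotation, _b=base, _c=scale, _o=f_star) -> float:
        return _b(_r @ (_c * (x - _s))) + _o

    return BenchmarkFunction(
        fid, dim, shift, rotation, f_star, func,
        manifest={"family": base.__name__, "scale": scale},
    )


def _make_hybrid(fid: str, dim: int, rng: np.random.Generator) -> BenchmarkFunction:
    names, props = _HYBRID_SPECS[fid]
    shift = rng.uniform(-80.0, 80.0, size=dim)
    rotation = _random_rotation(rng, dim)
    chunks = _partition(dim, props, rng)
    f_star = FUNCTION_OFFSETS[fid]
    parts = [(idx, *_HYBRID_COMPONENTS[name]) for idx, name in zip(chunks, names)]

    def func(x: np.ndarray, _s=shift, _r=rotation, _p=parts, _o=f_star) -> float:
        z = _r @ (x - _s)
        return sum(g(c * z[idx]) for idx, g, c in _p) + _o

    return BenchmarkFunction(
        fid, dim, shift, rotation, f_star, func,
        manifest={
            "family": "hybrid",
            "components": names,
            "proportions": props,
            "partition": [c.tolist() for c in chunks],
        },
    )


def _make_composition(fid: str, dim: int, rng: np.random.Generator) -> BenchmarkFunction:
    names, sigmas, lambdas, biases = _COMPOSITION_SPECS[fid]
    shifts = [rng.uniform(-80.0, 80.0, size=dim) for _ in names]
    rotations = [_random_rotation(rng, dim) for _ in names]
    f_star = FUNCTION_OFFSETS[fid]
    comps = [
        (shifts[i], rotations[i], *_HYBRID_COMPONENTS[names[i]],
         sigmas[i], lambdas[i], biases[i])
        for i in range(len(names))
    ]

    def func(x: np.ndarray, _c=comps, _o=f_star, _d=dim) -> float:
        weights, values = [], []
        for shift, rot, g, scale, sigma, lam, bias in _c:
            diff = x - shift
            d2 = float(np.sum(diff**2))
            if d2 == 0.0:
                w = 1e10
            else:
                w = np.exp(-d2 / (2.0 * _d * sigma**2)) / np.sqrt(d2)
            weights.append(w)
            values.append(lam * g(rot @ (scale * diff)) + bias)
        weights = np.asarray(weights)
        total = weights.sum()
        if total == 0.0:
            weights = np.full(len(_c), 1.0 / len(_c))
        else:
            weights = weights / total
        return float(np.dot(weights, values)) + _o

    return BenchmarkFunction(
        fid, dim, shifts[0], rotations[0], f_star, func,
        manifest={
            "family": "composition",
            "components": names,
            "sigmas": sigmas,
            "lambdas": lambdas,
            "biases": biases,
        },
    )


def make_suite(dim: int = 20, seed: int = 0) -> list[BenchmarkFunction]:
    """Build the ten-function suite with seeded synthetic shift/rotation
    data; bitwise reproducible for equal (dim, seed)."""
    if dim not in (2, 5, 10, 15, 20):
        raise ValueError("dim must be one of 2, 5, 10, 15, 20")
    rng = np.random.default_rng(seed)
    suite = [
        _make_basic("F1", dim, rng),
        _make_basic("F2", dim, rng),
        _make_basic("F3", dim, rng),
        _make_basic("F4", dim, rng),
        _make_hybrid("F5", dim, rng),
        _make_hybrid("F6", dim, rng),
        _make_hybrid("F7", dim, rng),
        _make_composition("F8", dim, rng),
        _make_composition("F9", dim, rng),
        _make_composition("F10", dim, rng),
    ]
    return suite


def suite_manifest(suite: list[BenchmarkFunction]) -> str:
    """JSON manifest of the suite's construction parameters."""
    return json.dumps(
        {fn.id: {"dim": fn.dim, "f_star": fn.f_star, **fn.manifest} for fn in suite},
        indent=2,
    )
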