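"""End-to-end multi-level thresholding segmentation.

The pipeline reads an 8-bit grayscale or RGB image, builds one
normalized histogram per channel, lets the chosen optimizer (SAR or
mSAR) maximize the chosen criterion (Otsu between-class variance or
fuzzy entropy) over agent vectors in [0, 255]^D, decodes the best agent
into thresholds, and renders a quantized image in which every class is
painted with its mean gray level (interval midpoint for empty classes)
so that fidelity metrics against the original are meaningful.

The optimizer only ever sees the 256-bin histogram, so objective cost
is independent of image size.  RGB channels are segmented independently
(no colorspace conversion); channel c of a run seeded with ``seed``
uses ``seed + c`` so the whole result is reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .obl import OblConfig, run_msar
from .objectives import (
    FuzzyParams,
    Histogram,
    ThresholdSet,
    decode_agent,
    fuzzy_entropy_objective,
    fuzzy_thresholds,
    normalized_histogram,
    otsu_objective,
)
from .sar import Bounds, SarConfig, run_sar

__all__ = ["SegmentationResult", "apply_thresholds", "segment_image", "make_objective"]


@dataclass(frozen=True)
class SegmentationResult:
    """Per-channel thresholds, objective values and convergence curves,
    plus the quantized rendering of the input."""

    thresholds: list[ThresholdSet]
    quantized: np.ndarray
    objective_values: list[float]
    convergence: list[np.ndarray]
    method: str
    algorithm: str
    n_thresholds: int
    seed: int
    config: dict = field(default_factory=dict)
    fuzzy_params: list[FuzzyParams] | None = None

    def save(self, out_dir, stem: str = "segmentation") -> None:
        """Write the quantized PNG, a JSON sidecar and CSV convergence."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        iio.imwrite(out / f"{stem}.png", self.quantized)
        sidecar = {
            "method": self.method,
            "algorithm": self.algorithm,
            "n_thresholds": self.n_thresholds,
            "seed": self.seed,
            "config": self.config,
            "thresholds": [t.values.tolist() for t in self.thresholds],
            "objective_values": self.objective_values,
        }
        (out / f"{stem}.json").write_text(json.dumps(sidecar, indent=2))
        frames = []
        for c, curve in enumerate(self.convergence):
            frames.append(
                pd.DataFrame(
                    {
                        "channel": c,
                        "iteration": np.arange(curve.size),
                        "best_fitness": curve,
                    }
                )
            )
        pd.concat(frames).to_csv(out / f"{stem}_convergence.csv", index=False)


def apply_thresholds(
    channel: np.ndarray, th: ThresholdSet
) -> tuple[np.ndarray, np.ndarray]:
    """Class map and class-mean quantization of one channel.

    A pixel of value g falls in class c = number of thresholds <= g.
    Quantized value = mean gray level of the pixels in that class;
    empty classes would render as their interval midpoint.
    """
    arr = np.asarray(channel)
    classes = np.searchsorted(th.values, arr.reshape(-1), side="right")
    n_classes = th.n_thresholds + 1
    edges = [0, *[int(t) for t in th.values], 256]
    flat = arr.reshape(-1).astype(float)
    levels = np.empty(n_classes)
    for c in range(n_classes):
        sel = classes == c
        if sel.any():
            levels[c] = flat[sel].mean()
        else:
            levels[c] = (edges[c] + edges[c + 1] - 1) / 2.0
    quant = np.round(levels[classes]).astype(arr.dtype).reshape(arr.shape)
    return classes.reshape(arr.shape), quant


def make_objective(
    hist: Histogram, n_thresholds: int, method: Literal["otsu", "fuzzy"]
):
    """Objective over raw agent vectors: decode, then score on ``hist``."""
    if method == "otsu":
        # precomputed cumulative sums: same summation as otsu_objective,
        # so values round-trip bitwise through the public scorer
        levels = np.arange(256, dtype=float)
        cp = np.concatenate([[0.0], np.cumsum(hist.p)])
        cm = np.concatenate([[0.0], np.cumsum(hist.p * levels)])
        mu_t = cm[-1]

        from .objectives import _enforce_strict

        def objective(x: np.ndarray) -> float:
            # inline decode (identical arithmetic to decode_agent, minus
            # the container construction) — values round-trip bitwise
            vals = _enforce_strict(np.round(np.clip(x, 1, 254)).astype(int))
            edges = np.concatenate([[0], vals, [256]])
            om = cp[edges[1:]] - cp[edges[:-1]]
            ms = cm[edges[1:]] - cm[edges[:-1]]
            mu = np.where(om > 0, ms / np.where(om > 0, om, 1.0), 0.0)
            return float(np.sum(om * (mu - mu_t) ** 2))
    elif method == "fuzzy":
        def objective(x: np.ndarray) -> float:
            return fuzzy_entropy_objective(
                hist, decode_agent(x, n_thresholds, "fuzzy")
            )
    else:
        raise ValueError("method must be 'otsu' or 'fuzzy'")
    return objective


def _load_image(image) -> np.ndarray:
    if isinstance(image, (str, Path)):
        image = iio.imread(image)
    arr = np.asarray(image)
    if arr.dtype != np.uint8:
        if np.issubdtype(arr.dtype, np.integer) and arr.min() >= 0 and arr.max() <= 255:
            arr = arr.astype(np.uint8)
        else:
            raise ValueError("expected an 8-bit image (values 0..255)")
    if arr.ndim == 2:
        return arr
    if arr.ndim == 3 and arr.shape[2] in (3, 4):
        return arr[..., :3]  # drop alpha
    raise ValueError("expected a 2-D grayscale or RGB image")


def segment_image(
    image,
    n_thresholds: int,
    method: Literal["otsu", "fuzzy"] = "otsu",
    algorithm: Literal["sar", "msar"] = "msar",
    config: SarConfig | None = None,
    obl: OblConfig | None = None,
) -> SegmentationResult:
    """Segment an 8-bit image by optimized multi-level thresholding."""
    if not 1 <= n_thresholds <= 20:
        raise ValueError("n_thresholds must lie in 1..20")
    arr = _load_image(image)
    config = config or SarConfig()
    channels = [arr] if arr.ndim == 2 else [arr[..., c] for c in range(3)]

    dim = n_thresholds if method == "otsu" else 3 * n_thresholds
    bounds = Bounds.cube(0.0, 255.0, dim)

    thresholds: list[ThresholdSet] = []
    objective_values: list[float] = []
    curves: list[np.ndarray] = []
    fuzzy_params: list[FuzzyParams] = []
    quant_channels: list[np.ndarray] = []

    for c, chan in enumerate(channels):
        hist = normalized_histogram(chan)
        objective = make_objective(hist, n_thresholds, method)
        chan_config = SarConfig(
            pop_size=config.pop_size,
            se=config.se,
            mu_max=config.mu_max,
            max_iters=config.max_iters,
            sense="maximize",
            eps=config.eps,
            mutation_ratio_p=config.mutation_ratio_p,
            seed=config.seed + c,
        )
        if algorithm == "msar":
            res = run_msar(objective, bounds, chan_config, obl)
        elif algorithm == "sar":
            res = run_sar(objective, bounds, chan_config)
        else:
            raise ValueError("algorithm must be 'sar' or 'msar'")

        decoded = decode_agent(res.best_position, n_thresholds, method)
        if method == "fuzzy":
            fuzzy_params.append(decoded)
            th = fuzzy_thresholds(decoded)
        else:
            th = decoded
        thresholds.append(th)
        objective_values.append(float(res.best_fitness))
        curves.append(res.convergence)
        _, quant = apply_thresholds(chan, th)
        quant_channels.append(quant)

    quantized = (
        quant_channels[0] if arr.ndim == 2 else np.stack(quant_channels, axis=-1)
    )
    return SegmentationResult(
        thresholds=thresholds,
        quantized=quantized,
        objective_values=objective_values,
        convergence=curves,
        method=method,
        algorithm=algorithm,
        n_thresholds=n_thresholds,
        seed=config.seed,
        config={
            "pop_size": config.pop_size,
            "se": config.se,
            "mu_max": config.mu_max,
            "max_iters": config.max_iters,
            "eps": config.eps,
        },
        fuzzy_params=fuzzy_params or None,
    )
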