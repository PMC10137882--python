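"""Non-parametric comparison of optimizer result tables.

Given an F x A matrix of per-problem mean results for A algorithms,
two standard tools rank the field:

* the Wilcoxon rank-sum (Mann-Whitney) test for whether two algorithms'
  run distributions differ, with the H = 1 iff p < alpha convention;
* Friedman mean ranks — per problem the algorithms are ranked 1..A
  (average ranks on ties), the per-algorithm means of those ranks are
  reported, and a final ordering ranks the algorithms by ascending mean
  rank (ties broken by column order, matching how published tables
  print the row).  The Friedman chi-square statistic and p-value are
  computed alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ResultsMatrix",
    "FriedmanResult",
    "wilcoxon_rank_sum",
    "friedman_mean_ranks",
    "load_reference_means",
]


@dataclass(frozen=True)
class ResultsMatrix:
    """F problems x A algorithms of mean objective values."""

    values: np.ndarray
    algorithms: list[str]
    problems: list[str]
    sense: Literal["minimize", "maximize"] = "minimize"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if not np.isfinite(v).all():
            raise ValueError("values must be finite")
        if v.shape[1] < 2:
            raise ValueError("need at least two algorithms")
        if v.shape[0] < 1:
            raise ValueError("need at least one problem")
        if len(self.algorithms) != v.shape[1] or len(self.problems) != v.shape[0]:
            raise ValueError("label lengths must match the matrix shape")
        if self.sense not in ("minimize", "maximize"):
            raise ValueError("sense must be 'minimize' or 'maximize'")
        object.__setattr__(self, "values", v)

    def to_csv(self, path) -> None:
        pd.DataFrame(self.values, index=self.problems, columns=self.algorithms).to_csv(
            path, index_label="problem"
        )

    @staticmethod
    def from_csv(path, sense: Literal["minimize", "maximize"] = "minimize") -> "ResultsMatrix":
        df = pd.read_csv(path, index_col=0)
        return ResultsMatrix(
            values=df.to_numpy(dtype=float),
            algorithms=[str(c) for c in df.columns],
            problems=[str(i) for i in df.index],
            sense=sense,
        )


@dataclass(frozen=True)
class FriedmanResult:
    mean_ranks: np.ndarray
    final_order: np.ndarray  # 1..A, 1 = best (lowest mean rank)
    chi_square: float
    p_value: float
    algorithms: list[str]


def wilcoxon_rank_sum(a, b, alpha: float = 0.05) -> tuple[float, int]:
    """Two-sided rank-sum test; returns (p, H) with H = 1 iff p < alpha.

    Exact enumeration when both samples are small (n + m <= 12) and
    tie-free; otherwise the normal approximation with tie correction.
    """
    a = np.asarray(a, dtype=float).reshape(-1)
    b = np.asarray(b, dtype=float).reshape(-1)
    if a.size == 0 or b.size == 0:
        raise ValueError("samples must be nonempty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (a.size + b.size <= 12 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    p = float(min(res.pvalue, 1.0))
    return p, int(p < alpha)


def _ordinal_ranks(values: np.ndarray) -> np.ndarray:
    """1..n ranks by ascending value, ties broken by position (stable)."""
    order = np.argsort(values, kind="stable")
    ranks = np.empty(values.size, dtype=int)
    ranks[order] = np.arange(1, values.size + 1)
    return ranks


def friedman_mean_ranks(m: ResultsMatrix) -> FriedmanResult:
    """Friedman mean ranks and the final ordering of the algorithms."""
    vals = m.values if m.sense == "minimize" else -m.values
    per_problem = np.apply_along_axis(sps.rankdata, 1, vals)
    mean_ranks = per_problem.mean(axis=0)

    n, k = vals.shape
    if n >= 2:
        chi2, p = sps.friedmanchisquare(*[vals[:, j] for j in range(k)])
    else:
        chi2, p = float("nan"), float("nan")
    return FriedmanResult(
        mean_ranks=mean_ranks,
        final_order=_ordinal_ranks(mean_ranks),
        chi_square=float(chi2),
        p_value=float(p),
        algorithms=list(m.algorithms),
    )


def load_reference_means() -> ResultsMatrix:
    """Packaged reference table: published mean results of eight
    metaheuristics (30 runs each) on the ten-function suite at D = 20,
    used to exercise the rank statistics."""
    with resources.as_file(
        resources.files("msar.data").joinpath("reference_means.csv")
    ) as path:
        return ResultsMatrix.from_csv(Path(path), sense="minimize")
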