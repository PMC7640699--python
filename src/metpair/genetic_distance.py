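"""CCF-based genetic distances between tumor samples.

Three definitions over paired CCF vectors x, y on the union mutation set
(a mutation absent from a sample contributes CCF 0 there):

Nei's genetic distance, treating each mutation as a biallelic locus with
allele frequencies (ccf, 1-ccf)::

    D = -ln [ sum(x_i y_i + (1-x_i)(1-y_i))
              / sqrt( sum(x_i^2 + (1-x_i)^2) * sum(y_i^2 + (1-y_i)^2) ) ]

the mean absolute CCF difference::

    D = sum |x_i - y_i| / n

and the (real-valued Tanimoto/) Jaccard distance::

    D = sum (x_i - y_i)^2 / ( sum x_i^2 + sum y_i^2 - sum x_i y_i )

All three are symmetric and zero at identity; mean-abs and Jaccard lie
in [0, 1] for CCFs in [0, 1].
"""

from __future__ import annotations

import itertools
import warnings
from typing import Callable, Sequence

import numpy as np


def _as_pair(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 1:
        raise ValueError("x and y must be equal-length 1-D vectors, length >= 1")
    for v, name in ((x, "x"), (y, "y")):
        if np.any(v < 0) or np.any(v > 1):
            raise ValueError(f"CCFs in {name} must lie in [0, 1]")
    return x, y


def nei_distance(x: Sequence[float], y: Sequence[float]) -> float:
    x, y = _as_pair(x, y)
    num = float(np.sum(x * y + (1 - x) * (1 - y)))
    jx = float(np.sum(x**2 + (1 - x) ** 2))
    jy = float(np.sum(y**2 + (1 - y) ** 2))
    if num <= 0:
        warnings.warn("zero locus-identity numerator; distance is infinite")
        return float("inf")
    return float(-np.log(num / np.sqrt(jx * jy)))


def mean_abs_ccf_distance(x: Sequence[float], y: Sequence[float]) -> float:
    x, y = _as_pair(x, y)
    return float(np.mean(np.abs(x - y)))


def jaccard_distance(x: Sequence[float], y: Sequence[float]) -> float:
    x, y = _as_pair(x, y)
    denom = float(np.sum(x**2) + np.sum(y**2) - np.sum(x * y))
    if denom == 0:
        raise ValueError("Jaccard distance undefined for two all-zero vectors")
    return float(np.sum((x - y) ** 2) / denom)


METRICS: dict[str, Callable] = {
    "nei": nei_distance,
    "meanabs": mean_abs_ccf_distance,
    "jaccard": jaccard_distance,
}


def average_pairwise_distance(
    regions: Sequence[Sequence[float]], metric: str = "nei"
) -> float:
    """Unweighted mean of the metric over all C(k, 2) region pairs.

    Used when a tumor has more than two sampled regions: the reported
    distance is the average over every possible two-region combination.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {sorted(METRICS)}")
    if len(regions) < 2:
        raise ValueError("need at least 2 regions")
    fn = METRICS[metric]
    vals = [fn(a, b) for a, b in itertools.combinations(regions, 2)]
    return float(np.mean(vals))
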