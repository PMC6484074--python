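"""Threshold-exceedance probabilities and verbal-scale classification.

At a grid node the conditional distribution of log plasma Se is Gaussian
(m, s2), so the probability that a woman's true concentration falls below a
threshold T (ng/mL) is

    p = Phi((ln T - m) / sqrt(s2))

with Phi the standard normal CDF.  With s2 = 0 the distribution is a point
mass and p = 1[exp(m) < T] (strict inequality).  Probabilities are
classified on an ordered verbal scale (calibrated uncertainty phrases) for
mapping, with the numeric bin edges carried into legends.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "ThresholdSet",
    "VerbalScale",
    "exceedance_probability",
    "classify_verbal",
    "map_exceedance",
]


@dataclass(frozen=True)
class ThresholdSet:
    """Named plasma Se deficiency thresholds in ng/mL.

    Defaults: optimal glutathione peroxidase 3 activity (GPx3, 84.9),
    optimal iodothyronine deiodinase activity (IDI, 64.8), and the Keshan
    disease risk level (KD, 30).
    """

    thresholds: dict = field(
        default_factory=lambda: {"GPx3": 84.9, "IDI": 64.8, "KD": 30.0}
    )

    def __post_init__(self) -> None:
        for name, t in self.thresholds.items():
            if not (t > 0 and np.isfinite(t)):
                raise ValueError(f"threshold {name} must be positive, got {t}")

    def items(self):
        return self.thresholds.items()


@dataclass(frozen=True)
class VerbalScale:
    """Ordered probability bins with calibrated-language labels.

    ``edges`` are interior bin edges in (0, 1), strictly increasing; with k
    edges there are k + 1 labels.  A probability p is assigned to the
    half-open bin [lower, upper), with p = 1 in the top bin.
    """

    edges: tuple = (0.10, 0.33, 0.66, 0.90)
    labels: tuple = (
        "very unlikely",
        "unlikely",
        "as likely as not",
        "likely",
        "very likely",
    )

    def __post_init__(self) -> None:
        e = np.asarray(self.edges, dtype=float)
        if np.any(np.diff(e) <= 0) or np.any(e <= 0) or np.any(e >= 1):
            raise ValueError("edges must be strictly increasing within (0, 1)")
        if len(self.labels) != len(self.edges) + 1:
            raise ValueError("need one more label than edges")

    def to_legend(self) -> dict:
        """Legend mapping: label -> [lower, upper) probability interval."""
        bounds = [0.0, *self.edges, 1.0]
        return {
            lab: [bounds[i], bounds[i + 1]] for i, lab in enumerate(self.labels)
        }


def exceedance_probability(dist, threshold: float) -> float:
    """P(true concentration < threshold) under the prediction distribution.

    ``dist`` is a PredictionDistribution (or anything with ``m`` and ``s2``).
    """
    if not (threshold > 0 and np.isfinite(threshold)):
        raise ValueError(f"threshold must be positive, got {threshold}")
    if dist.s2 < 0:
        raise ValueError("prediction variance must be non-negative")
    if dist.s2 == 0:
        return float(np.exp(dist.m) < threshold)
    return float(norm.cdf((np.log(threshold) - dist.m) / np.sqrt(dist.s2)))


def classify_verbal(p: float, scale: VerbalScale | None = None) -> str:
    """Verbal label of the half-open bin containing probability p."""
    if scale is None:
        scale = VerbalScale()
    if not (0 <= p <= 1):
        raise ValueError(f"probability must be in [0, 1], got {p}")
    idx = int(np.searchsorted(scale.edges, p, side="right"))
    if p == 1.0:
        idx = len(scale.labels) - 1
    return scale.labels[idx]


def map_exceedance(
    grid_predictions: pd.DataFrame,
    thresholds: ThresholdSet | None = None,
    scale: VerbalScale | None = None,
) -> pd.DataFrame:
    """Per-node exceedance probabilities and verbal classes.

    ``grid_predictions`` is the (x, y, m, s2, ...) frame from
    ``krige_grid``.  Returns one row per node with p_<name> and
    label_<name> columns per threshold; probabilities are monotone
    non-decreasing in the threshold by construction of the normal CDF.
    """
    if thresholds is None:
        thresholds = ThresholdSet()
    if scale is None:
        scale = VerbalScale()
    m = grid_predictions["m"].to_numpy(dtype=float)
    s2 = grid_predictions["s2"].to_numpy(dtype=float)
    if np.any(s2 < 0):
        raise ValueError("negative prediction variance")
    out = grid_predictions[["x", "y"]].copy()
    s = np.sqrt(s2)
    for name, t in thresholds.items():
        with np.errstate(divide="ignore"):
            zscore = np.where(s > 0, (np.log(t) - m) / np.where(s > 0, s, 1.0), np.inf)
        p = np.where(s > 0, norm.cdf(zscore), (np.exp(m) < t).astype(float))
        out[f"p_{name}"] = p
        out[f"label_{name}"] = [classify_verbal(pi, scale) for pi in p]
    return out
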