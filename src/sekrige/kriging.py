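"""Ordinary kriging of individual-level log plasma Se onto a grid.

The prediction target at a grid node is the log concentration of an
*unobserved individual* at that location, so the target variance is the
full sigma2_c + sigma2_h + sigma2_e, while the target-support covariance
carries only the spatial component (a new individual shares no household or
residual effect with any observation):

    c0_i = sigma2_c * rho(||x0 - x_cluster(i)||)

The OK system with unknown constant mean is

    [ C  1 ] [ lambda ]   [ c0 ]
    [ 1' 0 ] [ psi    ] = [ 1  ]

with C the full observation covariance from the fitted model.  The
prediction is m = lambda' z, and the kriging variance

    s2 = sigma2_total - lambda' c0 - psi.

The OK prediction is treated as the mean of the conditional (Gaussian)
distribution of the log value and s2 as its variance; exponentiating m
gives a median-unbiased central value on the ng/mL scale.

Kriging is global (every observation in every solve) with plug-in REML
parameters; the augmented matrix is factorized once per dataset and reused
for all nodes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import lu_factor, lu_solve
from shapely.geometry import Point, Polygon
from shapely.prepared import prep

from .covariance import assemble_covariance, matern_correlation
from .reml import FittedModel, NestedIndex

__all__ = [
    "PredictionGrid",
    "PredictionDistribution",
    "KrigingSystem",
    "build_grid",
    "krige_point",
    "krige_grid",
    "back_transform_median",
]


@dataclass(frozen=True)
class PredictionGrid:
    """Regular square lattice clipped to a boundary polygon.

    nodes : (m, 2) cell-center coordinates (km) of interior nodes
    resolution : lattice spacing (km)
    """

    nodes: np.ndarray
    resolution: float


@dataclass(frozen=True)
class PredictionDistribution:
    """Conditional distribution of log concentration at one location.

    m : OK prediction (log ng/mL); s2 : OK variance; lagrange : multiplier
    psi of the unbiasedness constraint (s2 = sigma2_total - lambda'c0 - psi).
    """

    m: float
    s2: float
    lagrange: float


def build_grid(boundary: Polygon, resolution: float) -> PredictionGrid:
    """Cell-center lattice at ``resolution`` km masked to the boundary."""
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    if boundary is None or boundary.is_empty:
        raise ValueError("boundary polygon is empty")
    minx, miny, maxx, maxy = boundary.bounds
    xs = np.arange(minx + resolution / 2, maxx, resolution)
    ys = np.arange(miny + resolution / 2, maxy, resolution)
    if xs.size == 0:
        xs = np.array([(minx + maxx) / 2])
    if ys.size == 0:
        ys = np.array([(miny + maxy) / 2])
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    prepared = prep(boundary)
    mask = np.fromiter(
        (prepared.contains(Point(xy)) for xy in pts), dtype=bool, count=len(pts)
    )
    nodes = pts[mask]
    if nodes.size == 0:
        # coarse lattice missed a small polygon entirely: fall back to the
        # representative point so callers always get >= 1 node
        rp = boundary.representative_point()
        nodes = np.array([[rp.x, rp.y]])
    return PredictionGrid(nodes=nodes, resolution=float(resolution))


class KrigingSystem:
    """Factorized global OK system for one dataset + fitted model.

    Builds the augmented matrix once; ``predict`` solves for any number of
    target locations.
    """

    def __init__(self, table: pd.DataFrame, model: FittedModel):
        if not model.converged:
            raise ValueError("refusing to krige from a non-converged model")
        if len(table) < 1:
            raise ValueError("need at least one observation")
        self.z = np.log(table["plasma_se"].to_numpy(dtype=float))
        self.index = NestedIndex.from_table(table)
        self.model = model
        n = len(self.z)
        C = assemble_covariance(
            self.index.cl_codes,
            self.index.hh_codes,
            model.components,
            model.matern,
            self.index.cluster_coords,
        )
        A = np.zeros((n + 1, n + 1))
        A[:n, :n] = C
        A[:n, n] = 1.0
        A[n, :n] = 1.0
        try:
            self._lu = lu_factor(A)
        except Exception as exc:  # pragma: no cover
            raise np.linalg.LinAlgError(f"singular kriging matrix: {exc}") from exc
        if not np.all(np.isfinite(self._lu[0])):
            raise np.linalg.LinAlgError(
                "singular kriging matrix (duplicate support points with zero "
                "nugget?)"
            )
        self.n = n

    def solve_weights(self, targets: np.ndarray):
        """OK weight vectors and Lagrange multipliers for target locations.

        Returns (lambda, psi) with lambda of shape (n_obs, n_targets); each
        weight column sums to 1 (the unbiasedness constraint).
        """
        targets = np.atleast_2d(np.asarray(targets, dtype=float))
        comp, matern = self.model.components, self.model.matern
        coords = self.index.cluster_coords
        d = np.sqrt(((targets[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
        rho = matern_correlation(d, matern)
        c0 = comp.sigma2_c * rho[:, self.index.cl_codes]  # (m, n)
        rhs = np.empty((self.n + 1, targets.shape[0]))
        rhs[: self.n] = c0.T
        rhs[self.n] = 1.0
        sol = lu_solve(self._lu, rhs)
        return sol[: self.n], sol[self.n], c0

    def predict(self, targets: np.ndarray) -> list[PredictionDistribution]:
        """OK prediction at each (x, y) row of ``targets``."""
        targets = np.atleast_2d(np.asarray(targets, dtype=float))
        comp = self.model.components
        lam, psi, c0 = self.solve_weights(targets)
        m = lam.T @ self.z
        s2 = comp.total - np.einsum("ij,ji->i", c0, lam) - psi
        s2 = np.where((s2 < 0) & (s2 > -1e-8), 0.0, s2)  # chop roundoff
        if np.any(s2 < 0):
            raise np.linalg.LinAlgError("negative kriging variance: singular system")
        return [
            PredictionDistribution(float(mi), float(s2i), float(pi))
            for mi, s2i, pi in zip(m, s2, psi)
        ]


def krige_point(
    x0, table: pd.DataFrame, model: FittedModel
) -> PredictionDistribution:
    """OK conditional distribution of an individual's log value at x0."""
    return KrigingSystem(table, model).predict(np.asarray(x0, dtype=float))[0]


def krige_grid(
    grid: PredictionGrid, table: pd.DataFrame, model: FittedModel
) -> pd.DataFrame:
    """OK predictions at every grid node.

    Returns a DataFrame (x, y, m, s2, median_ngml) where ``median_ngml`` is
    the median-unbiased back-transform exp(m).
    """
    system = KrigingSystem(table, model)
    preds = system.predict(grid.nodes)
    return pd.DataFrame(
        {
            "x": grid.nodes[:, 0],
            "y": grid.nodes[:, 1],
            "m": [p.m for p in preds],
            "s2": [p.s2 for p in preds],
            "median_ngml": [back_transform_median(p.m) for p in preds],
        }
    )


def back_transform_median(m: float) -> float:
    """Median-unbiased back-transform of a log-scale prediction.

    exp(m) is the median of the lognormal prediction distribution; the mean
    would be exp(m + s2/2), which this deliberately is not.
    """
    if not np.isfinite(m):
        raise ValueError("prediction must be finite")
    return float(np.exp(m))
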