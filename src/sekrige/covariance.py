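"""Matérn spatial correlation and the nested observation covariance.

The observation model for log plasma Se concentration is a linear mixed
model with a constant mean and three zero-mean random components:

    log(z_ijk) = mu + S(x_i) + H_ij + E_ijk

where ``S`` is a stationary, isotropic Gaussian random field over cluster
locations with variance ``sigma2_c`` and Matérn correlation, ``H_ij`` is an
independent between-household (within-cluster) effect with variance
``sigma2_h``, and ``E_ijk`` is the between-individual (within-household)
residual — which absorbs analytical error — with variance ``sigma2_e``.

The Matérn family is parameterised in the geoR convention

    rho(h) = [1 / (2^(nu-1) Gamma(nu))] (h/phi)^nu K_nu(h/phi)

so that ``nu = 0.5`` reduces exactly to the exponential model
``exp(-h/phi)`` and the effective range (correlation 0.05) is about
``3 phi``.  The distance parameter ``phi`` is in km; coordinates must be in
a projected planar CRS with km units — geographic coordinates have to be
projected upstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, kve

__all__ = [
    "MaternParams",
    "VarianceComponents",
    "matern_correlation",
    "effective_range",
    "assemble_covariance",
]


@dataclass(frozen=True)
class MaternParams:
    """Matérn correlation parameters: smoothness ``nu`` (dimensionless) and
    distance parameter ``phi`` (km)."""

    nu: float
    phi: float

    def __post_init__(self) -> None:
        if not (self.nu > 0 and np.isfinite(self.nu)):
            raise ValueError(f"smoothness nu must be positive, got {self.nu}")
        if not (self.phi > 0 and np.isfinite(self.phi)):
            raise ValueError(f"distance parameter phi must be positive, got {self.phi}")


@dataclass(frozen=True)
class VarianceComponents:
    """Log-scale variance components of the nested model.

    sigma2_c : between-cluster (spatially correlated) variance
    sigma2_h : between-household within-cluster variance
    sigma2_e : between-individual within-household variance
               (includes analytical error)
    """

    sigma2_c: float
    sigma2_h: float
    sigma2_e: float

    def __post_init__(self) -> None:
        for name in ("sigma2_c", "sigma2_h", "sigma2_e"):
            v = getattr(self, name)
            if not (v >= 0 and np.isfinite(v)):
                raise ValueError(f"{name} must be non-negative, got {v}")

    @property
    def total(self) -> float:
        """Marginal variance of a single log observation."""
        return self.sigma2_c + self.sigma2_h + self.sigma2_e


def matern_correlation(h, params: MaternParams):
    """Matérn correlation at separation distance ``h`` (km).

    Evaluated in log space through the exponentially scaled Bessel function
    ``kve`` so large smoothness values do not overflow.  ``rho(0) = 1`` and
    the function is continuous and monotone decreasing in ``h``.

    Parameters
    ----------
    h : float or array_like of non-negative distances (km)
    params : MaternParams

    Returns
    -------
    float or ndarray in (0, 1]
    """
    h = np.asarray(h, dtype=float)
    if np.any(h < 0):
        raise ValueError("distances must be non-negative")
    nu, phi = params.nu, params.phi
    u = h / phi
    out = np.ones_like(u)
    pos = u > 0
    if np.any(pos):
        up = u[pos]
        # log rho = -(nu-1) log 2 - log Gamma(nu) + nu log u + log K_nu(u)
        # with log K_nu(u) = log kve(nu, u) - u
        log_rho = (
            -(nu - 1.0) * np.log(2.0)
            - gammaln(nu)
            + nu * np.log(up)
            + np.log(kve(nu, up))
            - up
        )
        out[pos] = np.exp(log_rho)
    if out.ndim == 0:
        return float(out)
    return out


def effective_range(params: MaternParams, level: float = 0.05) -> float:
    """Distance (km) at which the correlation decays to ``level``.

    Solved numerically by bisection; for the exponential model (nu = 0.5)
    this is ``-phi * log(level)``, i.e. about ``3 phi`` at the conventional
    0.05 level.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    from scipy.optimize import brentq

    lo, hi = 1e-9, params.phi
    while matern_correlation(hi, params) > level:
        hi *= 2.0
        if hi > 1e9:
            raise RuntimeError("failed to bracket the effective range")
    return float(brentq(lambda d: matern_correlation(d, params) - level, lo, hi))


def cluster_correlation_matrix(coords: np.ndarray, matern: MaternParams) -> np.ndarray:
    """Matérn correlation matrix between cluster coordinates (k x 2, km)."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError("cluster coordinates must be a (k, 2) array")
    if not np.all(np.isfinite(coords)):
        raise ValueError("cluster coordinates must be finite")
    diff = coords[:, None, :] - coords[None, :, :]
    d = np.sqrt((diff**2).sum(axis=-1))
    return matern_correlation(d, matern)


def assemble_covariance(
    cluster_of_obs: np.ndarray,
    household_of_obs: np.ndarray,
    components: VarianceComponents,
    matern: MaternParams,
    cluster_coords: np.ndarray,
) -> np.ndarray:
    """Dense covariance matrix of the observed log values.

    V[i, j] = sigma2_c * rho(||x_ci - x_cj||)
              + sigma2_h * 1[same household]
              + sigma2_e * 1[i == j]

    Parameters
    ----------
    cluster_of_obs : integer codes (n,) mapping each observation to a row of
        ``cluster_coords``
    household_of_obs : integer codes (n,) identifying households (must be
        nested in clusters)
    components, matern : model parameters
    cluster_coords : (k, 2) planar coordinates in km

    Returns
    -------
    (n, n) symmetric positive-definite matrix with diagonal
    sigma2_c + sigma2_h + sigma2_e.
    """
    cluster_of_obs = np.asarray(cluster_of_obs)
    household_of_obs = np.asarray(household_of_obs)
    if cluster_of_obs.shape != household_of_obs.shape:
        raise ValueError("cluster and household index vectors differ in length")
    # a household spanning two clusters breaks the nesting assumption
    hh, first = np.unique(household_of_obs, return_index=True)
    hh_cluster = dict(zip(hh.tolist(), cluster_of_obs[first].tolist()))
    for h_id, c_id in zip(household_of_obs.tolist(), cluster_of_obs.tolist()):
        if hh_cluster[h_id] != c_id:
            raise ValueError(f"household {h_id} spans more than one cluster")

    R = cluster_correlation_matrix(np.asarray(cluster_coords), matern)
    V = components.sigma2_c * R[np.ix_(cluster_of_obs, cluster_of_obs)]
    same_house = household_of_obs[:, None] == household_of_obs[None, :]
    V = V + components.sigma2_h * same_house
    V[np.diag_indices_from(V)] += components.sigma2_e
    if components.total <= 0:
        raise ValueError("degenerate model: all variance components are zero")
    return V
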