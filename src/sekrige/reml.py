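"""Residual maximum likelihood for the nested spatial linear mixed model.

The model for the natural-log plasma Se concentration y is

    y = 1*mu + Z_c S + Z_h H + E

with a constant mean as the only fixed effect, a spatially correlated
between-cluster field S (variance sigma2_c, Matérn correlation), iid
household effects H (sigma2_h) and iid individual residuals E (sigma2_e).
The REML log-likelihood of V(theta) = sigma2_c R + sigma2_h Z_h Z_h' +
sigma2_e I is

    l_R = -1/2 [ (n-1) log 2pi + log|V| + log(1' V^-1 1) + y' P y ]

with P the REML projection; mu is profiled out by GLS.  Evaluation
exploits the nesting: the household + individual part A is block diagonal
by household with closed-form inverse and determinant, and the cluster
field enters through a k x k Woodbury correction (k = number of clusters),
so one evaluation costs O(n + k^3) rather than O(n^3).  The dense matrix
route via ``covariance.assemble_covariance`` gives the same value and
serves as the test oracle.

Variance components and the distance parameter are estimated by bounded
quasi-Newton search on log-transformed parameters with multiple starts
(REML surfaces of Matérn models can be multimodal); the smoothness
parameter is estimated by profile likelihood over a grid, following
standard geostatistical practice.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize

from .covariance import MaternParams, VarianceComponents, cluster_correlation_matrix

__all__ = [
    "NestedIndex",
    "FittedModel",
    "reml_loglik",
    "fit_variance_components",
    "profile_smoothness",
]

#: default smoothness grid for the profile likelihood
DEFAULT_NU_GRID = (0.1, 0.25, 0.5, 1.0, 1.5, 2.0)
#: variances below this are treated as effectively zero
VARIANCE_FLOOR = 1e-10
#: convergence tolerance on the log-likelihood
LOGLIK_TOL = 1e-6


@dataclass(frozen=True)
class NestedIndex:
    """Observation-to-cluster/household index of a nested survey.

    hh_codes, cl_codes : integer codes (n,) into households / clusters
    hh_cluster : cluster code of each household (n_households,)
    cluster_coords : (k, 2) planar km coordinates, one row per cluster code
    """

    hh_codes: np.ndarray
    cl_codes: np.ndarray
    hh_cluster: np.ndarray
    cluster_coords: np.ndarray

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "NestedIndex":
        hh_codes, hh_ids = pd.factorize(table["household_id"])
        cl_codes, cl_ids = pd.factorize(table["cluster_id"])
        first_obs = np.zeros(len(hh_ids), dtype=int)
        first_obs[hh_codes[::-1]] = np.arange(len(table))[::-1]
        hh_cluster = cl_codes[first_obs]
        if np.any(hh_cluster[hh_codes] != cl_codes):
            raise ValueError("households must be nested within clusters")
        coords = np.full((len(cl_ids), 2), np.nan)
        coords[cl_codes, 0] = table["x"].to_numpy(dtype=float)
        coords[cl_codes, 1] = table["y"].to_numpy(dtype=float)
        if not np.all(np.isfinite(coords)):
            raise ValueError("non-finite cluster coordinates")
        return cls(
            hh_codes=np.asarray(hh_codes),
            cl_codes=np.asarray(cl_codes),
            hh_cluster=np.asarray(hh_cluster),
            cluster_coords=coords,
        )

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_coords)

    @property
    def n_households(self) -> int:
        return len(self.hh_cluster)


def _reml_quantities(
    y: np.ndarray,
    index: NestedIndex,
    components: VarianceComponents,
    matern: MaternParams,
    R_chol: np.ndarray | None = None,
):
    """REML log-likelihood plus the GLS mean at these parameters.

    ``R_chol`` may carry a precomputed Cholesky factor of the cluster
    correlation matrix (it depends only on nu and phi, so optimizers that
    fix both can reuse it).
    """
    n = y.size
    if n < 2:
        raise ValueError("need at least 2 observations for REML")
    sc, sh, se = components.sigma2_c, components.sigma2_h, components.sigma2_e
    if se <= 0:
        m_h = np.bincount(index.hh_codes)
        if np.any(m_h > 1) or sh <= 0:
            raise ValueError(
                "singular covariance: sigma2_e = 0 duplicates rows within "
                "households"
            )
        # households of size one: fold sigma2_h into the diagonal
        se, sh = sh, 0.0

    m_h = np.bincount(index.hh_codes, minlength=index.n_households).astype(float)
    denom_h = se + m_h * sh  # per-household compound-symmetry eigenvalue

    hhsum_y = np.bincount(index.hh_codes, weights=y, minlength=index.n_households)
    ay = y / se - (sh / (se * denom_h))[index.hh_codes] * hhsum_y[index.hh_codes]
    logdet_A = float(np.sum((m_h - 1.0) * np.log(se) + np.log(denom_h)))

    y_Ainv_y = float(y @ ay)
    one_Ainv_y = float(ay.sum())
    one_Ainv_one = float(np.sum(m_h / denom_h))

    u_y = np.bincount(index.cl_codes, weights=ay, minlength=index.n_clusters)
    u_1 = np.bincount(
        index.hh_cluster, weights=m_h / denom_h, minlength=index.n_clusters
    )
    diag_M = u_1  # Z' A^-1 Z is diagonal because households nest in clusters

    if sc > 0:
        if R_chol is None:
            R = cluster_correlation_matrix(index.cluster_coords, matern)
            R_chol = np.linalg.cholesky(R + 1e-12 * np.eye(len(R)))
        Ls = np.sqrt(sc) * R_chol
        B = Ls.T @ (diag_M[:, None] * Ls)
        B[np.diag_indices_from(B)] += 1.0
        cB = cho_factor(B, lower=True)
        g_y = Ls.T @ u_y
        g_1 = Ls.T @ u_1
        a_y = cho_solve(cB, g_y)
        a_1 = cho_solve(cB, g_1)
        quad_yy = y_Ainv_y - float(g_y @ a_y)
        quad_1y = one_Ainv_y - float(g_1 @ a_y)
        quad_11 = one_Ainv_one - float(g_1 @ a_1)
        logdet_V = logdet_A + 2.0 * float(np.sum(np.log(np.diag(cB[0]))))
    else:
        quad_yy, quad_1y, quad_11 = y_Ainv_y, one_Ainv_y, one_Ainv_one
        logdet_V = logdet_A

    if quad_11 <= 0:
        raise np.linalg.LinAlgError("covariance matrix not positive definite")
    mu = quad_1y / quad_11
    y_P_y = quad_yy - quad_1y**2 / quad_11
    loglik = -0.5 * (
        (n - 1) * np.log(2.0 * np.pi) + logdet_V + np.log(quad_11) + y_P_y
    )
    return float(loglik), float(mu)


def reml_loglik(
    log_values: np.ndarray,
    index: NestedIndex,
    components: VarianceComponents,
    matern: MaternParams,
) -> float:
    """REML log-likelihood of the constant-mean nested spatial LMM.

    ``log_values`` are natural-log concentrations; the residual likelihood
    is invariant to adding a constant to them (the shift is absorbed by the
    profiled GLS mean).
    """
    y = np.asarray(log_values, dtype=float)
    if y.size != index.hh_codes.size:
        raise ValueError(
            f"{y.size} values but index describes {index.hh_codes.size} observations"
        )
    return _reml_quantities(y, index, components, matern)[0]


@dataclass
class FittedModel:
    """REML fit of the nested spatial LMM.

    nu_profile holds (nu, maximized REML log-likelihood) pairs when the
    smoothness was estimated by profile likelihood.
    """

    mu_hat: float
    components: VarianceComponents
    matern: MaternParams
    reml_loglik: float
    n_obs: int
    converged: bool
    phi_identifiable: bool = True
    nu_profile: list = field(default_factory=list)
    n_starts: int = 3

    def to_dict(self) -> dict:
        return {
            "mu_hat": self.mu_hat,
            "sigma2_c": self.components.sigma2_c,
            "sigma2_h": self.components.sigma2_h,
            "sigma2_e": self.components.sigma2_e,
            "nu": self.matern.nu,
            "phi": self.matern.phi,
            "reml_loglik": self.reml_loglik,
            "n_obs": self.n_obs,
            "converged": self.converged,
            "phi_identifiable": self.phi_identifiable,
            "nu_profile": [list(p) for p in self.nu_profile],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FittedModel":
        return cls(
            mu_hat=d["mu_hat"],
            components=VarianceComponents(d["sigma2_c"], d["sigma2_h"], d["sigma2_e"]),
            matern=MaternParams(d["nu"], d["phi"]),
            reml_loglik=d["reml_loglik"],
            n_obs=d["n_obs"],
            converged=d["converged"],
            phi_identifiable=d.get("phi_identifiable", True),
            nu_profile=[tuple(p) for p in d.get("nu_profile", [])],
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def load(cls, path) -> "FittedModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _anova_start(y: np.ndarray, index: NestedIndex) -> tuple[float, float, float]:
    """Method-of-moments starting values for the three variance components."""
    df = pd.DataFrame({"y": y, "hh": index.hh_codes, "cl": index.cl_codes})
    within_hh = df.groupby("hh")["y"].var(ddof=1).dropna()
    total = float(np.var(y, ddof=1))
    s2_e = float(within_hh.mean()) if len(within_hh) else 0.3 * total
    hh_means = df.groupby(["cl", "hh"])["y"].mean().reset_index()
    within_cl = hh_means.groupby("cl")["y"].var(ddof=1).dropna()
    m_bar = float(np.bincount(index.hh_codes).mean())
    s2_h = max(float(within_cl.mean()) - s2_e / m_bar, 0.05 * total) if len(within_cl) else 0.1 * total
    cl_means = df.groupby("cl")["y"].mean()
    s2_c = max(float(cl_means.var(ddof=1)) - s2_h / 2, 0.1 * total)
    return s2_c, max(s2_h, 1e-4), max(s2_e, 1e-4)


def fit_variance_components(
    table: pd.DataFrame,
    nu: float = 0.5,
    start: tuple | None = None,
    n_starts: int = 3,
    maxiter: int = 200,
) -> FittedModel:
    """Estimate (sigma2_c, sigma2_h, sigma2_e, phi) by REML at fixed nu.

    The optimizer works on log-transformed parameters (L-BFGS-B, bounded)
    from ``n_starts`` starting points; the best local optimum is kept.
    Non-convergence is reported through the ``converged`` flag rather than
    an exception.  When the spatial variance is estimated at (effectively)
    zero, phi is unidentifiable and ``phi_identifiable`` is False.

    Parameters
    ----------
    table : SurveyTable with positive ``plasma_se`` in ng/mL; the natural
        log transform is applied internally.
    nu : fixed Matérn smoothness.
    start : optional (sigma2_c, sigma2_h, sigma2_e, phi) override for the
        first start.
    """
    y = np.log(table["plasma_se"].to_numpy(dtype=float))
    index = NestedIndex.from_table(table)
    if index.n_clusters < 2:
        raise ValueError(
            "need at least 2 clusters to estimate a between-cluster component"
        )
    coords = index.cluster_coords
    diff = coords[:, None, :] - coords[None, :, :]
    dists = np.sqrt((diff**2).sum(-1))
    d_max = float(dists.max())
    if d_max <= 0:
        raise ValueError("all clusters share one coordinate; phi inestimable")

    var_y = float(np.var(y, ddof=1))
    lo_v, hi_v = np.log(VARIANCE_FLOOR), np.log(max(10.0 * var_y, 1.0))
    lo_p, hi_p = np.log(d_max * 1e-3), np.log(2.0 * d_max)
    bounds = [(lo_v, hi_v)] * 3 + [(lo_p, hi_p)]

    # the cluster correlation only depends on phi here, but phi moves during
    # optimisation, so the Cholesky cannot be cached across evaluations
    def nll(x: np.ndarray) -> float:
        sc, sh, se, phi = np.exp(x)
        try:
            ll, _ = _reml_quantities(
                y,
                index,
                VarianceComponents(sc, sh, se),
                MaternParams(nu, phi),
            )
        except np.linalg.LinAlgError:
            return 1e10
        if not np.isfinite(ll):
            return 1e10
        return -ll

    s2_c0, s2_h0, s2_e0 = _anova_start(y, index)
    starts = [
        (s2_c0, s2_h0, s2_e0, 0.1 * d_max),
        (var_y / 3, var_y / 3, var_y / 3, 0.3 * d_max),
        (0.8 * var_y, 0.1 * var_y, 0.1 * var_y, 0.03 * d_max),
    ]
    if start is not None:
        starts[0] = tuple(start)
    starts = starts[: max(1, n_starts)]

    best = None
    converged = False
    for s in starts:
        x0 = np.clip(np.log(np.asarray(s, dtype=float)),
                     [lo_v, lo_v, lo_v, lo_p], [hi_v, hi_v, hi_v, hi_p])
        res = minimize(
            nll,
            x0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": maxiter, "ftol": LOGLIK_TOL},
        )
        if best is None or res.fun < best.fun:
            best = res
        converged = converged or bool(res.success)

    sc, sh, se, phi = np.exp(best.x)
    sc = 0.0 if sc <= 2 * VARIANCE_FLOOR else float(sc)
    sh = 0.0 if sh <= 2 * VARIANCE_FLOOR else float(sh)
    components = VarianceComponents(sc, sh, float(se))
    matern = MaternParams(nu, float(phi))
    ll, mu = _reml_quantities(y, index, components, matern)
    phi_ident = sc > 1e-6 * max(components.total, 1e-12)
    return FittedModel(
        mu_hat=mu,
        components=components,
        matern=matern,
        reml_loglik=ll,
        n_obs=y.size,
        converged=converged,
        phi_identifiable=bool(phi_ident),
        n_starts=len(starts),
    )


def profile_smoothness(
    table: pd.DataFrame,
    nu_grid=DEFAULT_NU_GRID,
    n_starts: int = 3,
) -> FittedModel:
    """Estimate the Matérn smoothness by profile likelihood over a grid.

    Fits the variance components at each nu and returns the fit with the
    largest maximized REML log-likelihood; ties break toward smaller nu
    (parsimony).  The full (nu, log-likelihood) profile is stored on the
    returned model.
    """
    grid = sorted(float(v) for v in nu_grid)
    if not grid:
        raise ValueError("nu_grid must be non-empty")
    fits: list[FittedModel] = []
    failures: list[str] = []
    for nu in grid:
        try:
            fits.append(fit_variance_components(table, nu=nu, n_starts=n_starts))
        except Exception as exc:  # pragma: no cover - aggregated below
            failures.append(f"nu={nu}: {exc}")
    if not fits:
        raise RuntimeError(
            "profile likelihood failed at every grid point: " + "; ".join(failures)
        )
    # ties toward smaller nu: strict improvement required to switch
    best = fits[0]
    for f in fits[1:]:
        if f.reml_loglik > best.reml_loglik + 1e-9:
            best = f
    best.nu_profile = [(f.matern.nu, f.reml_loglik) for f in fits]
    return best
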