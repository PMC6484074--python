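"""Synthetic national micronutrient survey generator.

Emulates the sampling structure of a cluster survey of plasma selenium
status: clusters (enumeration areas) scattered over a country-scale region,
households nested in clusters, individuals nested in households, and a
lognormal outcome whose log-scale variation decomposes into a spatially
correlated between-cluster field plus independent household and individual
effects.  Every downstream stage of the pipeline (REML fitting, kriging,
exceedance mapping, cross-validation, prevalence tables) is testable
against data drawn from this generator because the generator inverts
exactly the model those stages assume.

Random number use is ordered deterministically — design first (cluster
coordinates, urban flags, wealth quintiles), then the spatial field S, then
household effects H, then individual effects E — so a seed reproduces the
same survey across versions.

The default region is an axis-aligned 160 km x 850 km rectangle (a
Malawi-like aspect ratio) in arbitrary planar km; reprojection of real
coordinates is the caller's responsibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon, box
from shapely.prepared import prep

from .covariance import MaternParams, VarianceComponents, cluster_correlation_matrix

__all__ = [
    "SurveyDesign",
    "GenerativeParams",
    "default_region",
    "generate_design",
    "simulate_survey",
    "attach_proximity_covariates",
]

#: Survey table column order used throughout the package.
SURVEY_COLUMNS = [
    "individual_id",
    "household_id",
    "cluster_id",
    "x",
    "y",
    "urban",
    "group",
    "wealth_quintile",
    "plasma_se",
]


def default_region(width_km: float = 160.0, height_km: float = 850.0) -> Polygon:
    """Axis-aligned rectangular study region in planar km."""
    return box(0.0, 0.0, width_km, height_km)


@dataclass(frozen=True)
class SurveyDesign:
    """Nested sampling design: clusters > households > individuals.

    clusters : DataFrame (cluster_id, x, y, urban)
    households : DataFrame (household_id, cluster_id)
    individuals : DataFrame (individual_id, household_id, group,
        wealth_quintile)
    """

    clusters: pd.DataFrame
    households: pd.DataFrame
    individuals: pd.DataFrame
    region: Polygon = field(repr=False, default=None)

    def __post_init__(self) -> None:
        cids = self.clusters["cluster_id"]
        if cids.duplicated().any():
            raise ValueError("cluster ids must be unique")
        if not self.households["cluster_id"].isin(set(cids)).all():
            raise ValueError("household references a non-existent cluster")
        if not (
            self.individuals["household_id"]
            .isin(set(self.households["household_id"]))
            .all()
        ):
            raise ValueError("individual references a non-existent household")

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)


@dataclass(frozen=True)
class GenerativeParams:
    """Parameters of the lognormal nested spatial model.

    mu : mean of natural-log plasma Se (log ng/mL) — the model's only
        fixed effect
    components : log-scale variance components
    matern : spatial correlation of the between-cluster field
    wealth_gradient : optional monotone shift of mu per wealth quintile
        step (log units per quintile, centred on quintile 3); 0 disables it
    """

    mu: float
    components: VarianceComponents
    matern: MaternParams
    wealth_gradient: float = 0.0

    @classmethod
    def malawi_like(cls) -> "GenerativeParams":
        """Defaults on the scale of the Malawi national survey fit:
        log-scale variances 0.15 / 0.018 / 0.028 (cluster / household /
        individual), exponential correlation with a 39.4 km distance
        parameter, and mu set so the marginal median is 78.4 ng/mL."""
        return cls(
            mu=float(np.log(78.4)),
            components=VarianceComponents(
                sigma2_c=0.15, sigma2_h=0.018, sigma2_e=0.028
            ),
            matern=MaternParams(nu=0.5, phi=39.4),
        )


def _sample_points_in_polygon(
    region: Polygon, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Uniform points inside a polygon by rejection from its bounding box.

    Exact coordinate duplicates are resampled so spatial covariance
    matrices stay positive definite by construction.
    """
    if region is None or region.is_empty or region.area <= 0:
        raise ValueError("region polygon is empty or degenerate")
    minx, miny, maxx, maxy = region.bounds
    prepared = prep(region)
    pts: list[tuple[float, float]] = []
    seen: set[tuple[float, float]] = set()
    # cap guards against pathological slivers where acceptance is ~0
    max_draws = max(10_000, 1000 * n)
    draws = 0
    while len(pts) < n:
        if draws > max_draws:
            raise RuntimeError(
                "rejection sampling failed: polygon area is a vanishing "
                "fraction of its bounding box"
            )
        m = max(2 * (n - len(pts)), 16)
        xs = rng.uniform(minx, maxx, m)
        ys = rng.uniform(miny, maxy, m)
        draws += m
        for xy in zip(xs, ys):
            if len(pts) == n:
                break
            if xy in seen:
                continue
            if prepared.contains(Point(xy)):
                pts.append(xy)
                seen.add(xy)
    return np.asarray(pts)


def generate_design(
    n_clusters: int,
    urban_fraction: float,
    households_per_cluster: int,
    individuals_per_household: int,
    region: Polygon | None = None,
    seed: int = 0,
    group: str = "WRA",
) -> SurveyDesign:
    """Draw a balanced nested survey design.

    Cluster locations are uniform over the region; ``round(n_clusters *
    urban_fraction)`` clusters are flagged urban at random.  Wealth
    quintiles are assigned independently uniform on 1-5.

    Note on identifiability: with a single individual per household the
    household and individual variance components are confounded; use at
    least 2 individuals per household when both are to be estimated.
    """
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    if households_per_cluster < 1 or individuals_per_household < 1:
        raise ValueError("household and individual counts must be >= 1")
    if not 0 <= urban_fraction <= 1:
        raise ValueError("urban_fraction must be in [0, 1]")
    if region is None:
        region = default_region()

    rng = np.random.default_rng(seed)
    coords = _sample_points_in_polygon(region, n_clusters, rng)
    n_urban = int(round(n_clusters * urban_fraction))
    urban = np.zeros(n_clusters, dtype=bool)
    urban[rng.choice(n_clusters, size=n_urban, replace=False)] = True

    clusters = pd.DataFrame(
        {
            "cluster_id": np.arange(1, n_clusters + 1),
            "x": coords[:, 0],
            "y": coords[:, 1],
            "urban": urban,
        }
    )
    hh_cluster = np.repeat(clusters["cluster_id"].to_numpy(), households_per_cluster)
    households = pd.DataFrame(
        {
            "household_id": np.arange(1, len(hh_cluster) + 1),
            "cluster_id": hh_cluster,
        }
    )
    ind_house = np.repeat(
        households["household_id"].to_numpy(), individuals_per_household
    )
    individuals = pd.DataFrame(
        {
            "individual_id": np.arange(1, len(ind_house) + 1),
            "household_id": ind_house,
            "group": group,
            "wealth_quintile": rng.integers(1, 6, size=len(ind_house)),
        }
    )
    return SurveyDesign(clusters, households, individuals, region)


def simulate_survey(
    design: SurveyDesign, params: GenerativeParams, seed: int = 0
) -> pd.DataFrame:
    """Simulate plasma Se concentrations on a design.

    log(plasma_se) = mu + S(cluster) + H(household) + E(individual), with S
    a zero-mean Gaussian field (variance sigma2_c, Matérn correlation) over
    cluster locations, H and E independent zero-mean Gaussians with
    variances sigma2_h and sigma2_e.  Values are returned on the natural
    ng/mL scale.  Draw order is S, then H, then E.
    """
    rng = np.random.default_rng(seed)
    comp, matern = params.components, params.matern

    clusters = design.clusters.reset_index(drop=True)
    coords = clusters[["x", "y"]].to_numpy(dtype=float)
    k = len(clusters)

    if comp.sigma2_c > 0:
        d = coords[:, None, :] - coords[None, :, :]
        dist = np.sqrt((d**2).sum(axis=-1))
        if np.any(dist[~np.eye(k, dtype=bool)] == 0):
            raise ValueError(
                "duplicate cluster coordinates with sigma2_c > 0 make the "
                "spatial covariance singular; regenerate the design"
            )
        R = cluster_correlation_matrix(coords, matern)
        L = np.linalg.cholesky(R + 1e-12 * np.eye(k))
        s_cluster = np.sqrt(comp.sigma2_c) * (L @ rng.standard_normal(k))
    else:
        s_cluster = np.zeros(k)

    households = design.households.reset_index(drop=True)
    h_house = (
        np.sqrt(comp.sigma2_h) * rng.standard_normal(len(households))
        if comp.sigma2_h > 0
        else np.zeros(len(households))
    )
    individuals = design.individuals.reset_index(drop=True)
    e_ind = (
        np.sqrt(comp.sigma2_e) * rng.standard_normal(len(individuals))
        if comp.sigma2_e > 0
        else np.zeros(len(individuals))
    )

    cl_pos = pd.Series(np.arange(k), index=clusters["cluster_id"])
    hh_pos = pd.Series(np.arange(len(households)), index=households["household_id"])
    ind_hh = hh_pos[individuals["household_id"]].to_numpy()
    ind_cl = cl_pos[households["cluster_id"].to_numpy()[ind_hh]].to_numpy()

    log_se = params.mu + s_cluster[ind_cl] + h_house[ind_hh] + e_ind
    if params.wealth_gradient != 0.0:
        log_se = log_se + params.wealth_gradient * (
            individuals["wealth_quintile"].to_numpy() - 3
        )

    table = pd.DataFrame(
        {
            "individual_id": individuals["individual_id"],
            "household_id": individuals["household_id"],
            "cluster_id": households["cluster_id"].to_numpy()[ind_hh],
            "x": coords[ind_cl, 0],
            "y": coords[ind_cl, 1],
            "urban": clusters["urban"].to_numpy()[ind_cl],
            "group": individuals["group"],
            "wealth_quintile": individuals["wealth_quintile"],
            "plasma_se": np.exp(log_se),
        }
    )
    return table[SURVEY_COLUMNS]


def attach_proximity_covariates(
    table: pd.DataFrame, vertisol_features, water_features
) -> pd.DataFrame:
    """Add minimum planar distances (km) to soil and water features.

    ``dist_vertisol`` and ``dist_water`` are the Euclidean distance from
    each record's cluster coordinate to the nearest feature; points inside
    a polygon feature get distance 0.  Features must be shapely geometries
    in the same planar km CRS as the table coordinates.
    """
    vertisols = list(vertisol_features)
    waters = list(water_features)
    if not vertisols or not waters:
        raise ValueError("feature collections must be non-empty")

    out = table.copy()
    pts = [Point(xy) for xy in zip(out["x"], out["y"])]
    out["dist_vertisol"] = [min(g.distance(p) for g in vertisols) for p in pts]
    out["dist_water"] = [min(g.distance(p) for g in waters) for p in pts]
    return out
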