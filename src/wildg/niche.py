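"""Climatic niche construction: PCA over distribution cells, population
projection, niche distances, and great-circle geographic distances.

The niche space is a PCA of eight temperature variables (annual mean, mean
diurnal range, seasonality, max of warmest month, min of coldest month,
annual range, mean of warmest quarter, mean of coldest quarter) over every
grid cell inside the species' distribution mask.  The origin of the PC
space — the multivariate mean of masked cells — is taken as the niche
center, and populations are located by projecting their local climate onto
the first two axes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0

CLIMATE_VARS = [
    "t_annual_mean",
    "t_diurnal_range",
    "t_seasonality",
    "t_max_warmest",
    "t_min_coldest",
    "t_annual_range",
    "t_mean_warmest_q",
    "t_mean_coldest_q",
]

#: temperature "level" variables expected to load together on PC1 when the
#: grid has a dominant warm-cold gradient
LEVEL_VARS = ["t_annual_mean", "t_max_warmest", "t_min_coldest", "t_mean_coldest_q"]


@dataclass
class ClimateGrid:
    """Lattice of climate cells with a distribution mask.

    cells: DataFrame with columns cell_id, lon, lat, mask (bool) and the
    eight CLIMATE_VARS columns.
    """

    cells: pd.DataFrame

    def __post_init__(self):
        missing = set(CLIMATE_VARS) - set(self.cells.columns)
        if missing:
            raise ValueError(f"climate grid missing variable(s): {sorted(missing)}")
        if int(self.cells["mask"].sum()) < 1:
            raise ValueError("climate grid has no masked (in-distribution) cells")

    @property
    def masked(self) -> pd.DataFrame:
        return self.cells[self.cells["mask"].astype(bool)]

    def write_csv(self, path) -> None:
        self.cells.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "ClimateGrid":
        return cls(pd.read_csv(path))


@dataclass
class NicheSpace:
    """Fitted climate PCA: centering/scaling constants, loadings, explained
    variance fractions, and the masked-cell scores."""

    mean: np.ndarray
    scale: np.ndarray
    loadings: np.ndarray          # (8, n_axes) columns = axes
    explained_fraction: np.ndarray
    cell_scores: pd.DataFrame     # cell_id + pc1..pc8 for masked cells
    variables: list

    def transform(self, values: np.ndarray) -> np.ndarray:
        """Project rows of raw climate values into PC space."""
        z = (np.atleast_2d(values) - self.mean) / self.scale
        return z @ self.loadings


@dataclass
class PopulationProjection:
    """Populations located in niche space."""

    table: pd.DataFrame  # population, lon, lat, pc1, pc2, center_distance
    local_values: pd.DataFrame


def fit_niche_pca(grid: ClimateGrid, scale: bool = True) -> NicheSpace:
    """PCA of the eight climate variables over masked cells.

    Variables are centered and (by default) scaled to unit variance; axes
    are ordered by decreasing variance and signed so each axis's largest-
    magnitude loading is positive.
    """
    masked = grid.masked
    if len(masked) < 10:
        raise ValueError("need at least 10 masked cells for the niche PCA")
    X = masked[CLIMATE_VARS].to_numpy(float)
    sd = X.std(axis=0, ddof=1)
    for name, s in zip(CLIMATE_VARS, sd):
        if s == 0:
            raise ValueError(f"climate variable {name!r} is constant over the mask")
    mean = X.mean(axis=0)
    scl = sd if scale else np.ones_like(sd)
    Z = (X - mean) / scl
    # SVD-based PCA; deterministic and exact for 8 columns
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    var = s**2 / (len(Z) - 1)
    frac = var / var.sum()
    loadings = Vt.T
    for j in range(loadings.shape[1]):
        k = np.argmax(np.abs(loadings[:, j]))
        if loadings[k, j] < 0:
            loadings[:, j] = -loadings[:, j]
    scores = Z @ loadings
    cell_scores = pd.DataFrame(
        scores, columns=[f"pc{j + 1}" for j in range(scores.shape[1])]
    )
    cell_scores.insert(0, "cell_id", masked["cell_id"].to_numpy())
    return NicheSpace(
        mean=mean,
        scale=scl,
        loadings=loadings,
        explained_fraction=frac,
        cell_scores=cell_scores,
        variables=list(CLIMATE_VARS),
    )


def _nearest_cells(grid: ClimateGrid, lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
    cells = grid.cells
    glon = cells["lon"].to_numpy(float)
    glat = cells["lat"].to_numpy(float)
    lo, hi = glon.min(), glon.max()
    la, ha = glat.min(), glat.max()
    # half a cell of slack at the borders
    dlon = np.median(np.diff(np.unique(glon))) if len(np.unique(glon)) > 1 else 1.0
    dlat = np.median(np.diff(np.unique(glat))) if len(np.unique(glat)) > 1 else 1.0
    out = []
    for x, y in zip(lon, lat):
        if not (lo - dlon <= x <= hi + dlon and la - dlat <= y <= ha + dlat):
            raise ValueError(f"site ({x}, {y}) lies outside the climate grid")
        d2 = (glon - x) ** 2 + (glat - y) ** 2
        out.append(int(np.argmin(d2)))
    return np.asarray(out)


def project_populations(
    space: NicheSpace, sites: pd.DataFrame, grid: ClimateGrid
) -> PopulationProjection:
    """Locate populations in niche space.

    sites: DataFrame with columns population, lon, lat.  Local climate is
    the nearest grid cell's values (raster-extraction semantics, no
    interpolation); scores use the stored centering/scaling/loadings; the
    distance to the niche center is the (pc1, pc2) Euclidean norm.
    """
    import warnings

    rows = _nearest_cells(grid, sites["lon"].to_numpy(float), sites["lat"].to_numpy(float))
    cells = grid.cells.iloc[rows]
    off_mask = ~cells["mask"].astype(bool).to_numpy()
    if off_mask.any():
        warnings.warn(
            f"{int(off_mask.sum())} site(s) fall on unmasked cells; projecting anyway",
            stacklevel=2,
        )
    local = cells[CLIMATE_VARS].to_numpy(float)
    scores = space.transform(local)
    table = pd.DataFrame(
        {
            "population": sites["population"].to_numpy(),
            "lon": sites["lon"].to_numpy(float),
            "lat": sites["lat"].to_numpy(float),
            "pc1": scores[:, 0],
            "pc2": scores[:, 1],
        }
    )
    table["center_distance"] = np.hypot(table["pc1"], table["pc2"])
    local_df = pd.DataFrame(local, columns=CLIMATE_VARS)
    local_df.insert(0, "population", table["population"].to_numpy())
    return PopulationProjection(table=table, local_values=local_df)


def niche_distances(proj: PopulationProjection) -> pd.DataFrame:
    """m x m Euclidean distances among populations in (pc1, pc2)."""
    t = proj.table
    if len(t) < 2:
        raise ValueError("need at least 2 populations")
    xy = t[["pc1", "pc2"]].to_numpy(float)
    diff = xy[:, None, :] - xy[None, :, :]
    D = np.sqrt((diff**2).sum(-1))
    return pd.DataFrame(D, index=t["population"], columns=t["population"])


def geographic_distances(sites: pd.DataFrame) -> pd.DataFrame:
    """Great-circle distances (km, spherical earth R=6371) among sites."""
    lat = np.radians(sites["lat"].to_numpy(float))
    lon = np.radians(sites["lon"].to_numpy(float))
    if np.any(np.abs(sites["lat"].to_numpy(float)) > 90):
        raise ValueError("latitude outside [-90, 90]")
    sin_lat = np.sin(lat)
    cos_lat = np.cos(lat)
    cos_dlon = np.cos(lon[:, None] - lon[None, :])
    cosang = np.clip(
        sin_lat[:, None] * sin_lat[None, :] + cos_lat[:, None] * cos_lat[None, :] * cos_dlon,
        -1.0,
        1.0,
    )
    D = EARTH_RADIUS_KM * np.arccos(cosang)
    np.fill_diagonal(D, 0.0)
    labels = sites["population"].to_numpy()
    return pd.DataFrame(D, index=labels, columns=labels)
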