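"""Synthetic multi-population study generator.

Emulates the structure of long-term monitored passerine datasets: several
populations followed for decades, overlapping generations with immigrant
founders entering any year, three morphological traits (tarsus, wing,
mass) measured with repeats on both sexes, three life-history traits
(laying date, clutch size, fledging success) measured on females, and a
European-style climate field with a dominant warm-cold gradient.  Ground
truth (per-population G and the full architecture) is retained so every
downstream stage can be tested for recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .niche import CLIMATE_VARS, ClimateGrid
from .pedigree import UNKNOWN, Pedigree, from_frame, inbreeding

MORPH_TRAITS = ["tarsus", "wing", "mass"]
LH_TRAITS = ["laying_date", "clutch_size", "fledging_success"]


def psd_sqrt(M: np.ndarray) -> np.ndarray:
    """Matrix square root of a PSD matrix (eigenvalues clipped at zero);
    exact for the zero matrix, unlike a jittered Cholesky."""
    w, V = np.linalg.eigh(0.5 * (M + M.T))
    return V * np.sqrt(np.maximum(w, 0.0))


def _psd_project(M: np.ndarray, floor: float = 1e-8) -> np.ndarray:
    """Clip eigenvalues at a small positive floor; symmetrize."""
    M = 0.5 * (M + M.T)
    w, V = np.linalg.eigh(M)
    w = np.maximum(w, floor)
    return (V * w) @ V.T


def _check_psd(M: np.ndarray, name: str) -> np.ndarray:
    M = np.asarray(M, float)
    if not np.allclose(M, M.T, atol=1e-10):
        raise ValueError(f"{name} must be symmetric")
    w = np.linalg.eigvalsh(M)
    if w.min() < -1e-8:
        raise ValueError(f"{name} is not positive semidefinite (min eig {w.min():.3g})")
    return 0.5 * (M + M.T)


@dataclass
class TraitArchitecture:
    """Ground-truth variance components and fixed effects for one trait group."""

    traits: list
    G: np.ndarray
    PE: np.ndarray
    Y: np.ndarray
    R: np.ndarray
    obs_var: np.ndarray | None = None  # per-trait observer variance, None = no term
    group: str = "morphology"          # "morphology" | "life_history"
    intercept: np.ndarray | None = None
    beta_age: np.ndarray | None = None
    beta_age2: np.ndarray | None = None
    beta_sex: np.ndarray | None = None
    beta_date: np.ndarray | None = None

    def __post_init__(self):
        n = len(self.traits)
        for nm in ("G", "PE", "Y", "R"):
            M = _check_psd(getattr(self, nm), nm)
            if M.shape != (n, n):
                raise ValueError(f"{nm} has shape {M.shape}, expected {(n, n)}")
            setattr(self, nm, M)
        for nm in ("intercept", "beta_age", "beta_age2", "beta_sex", "beta_date"):
            v = getattr(self, nm)
            setattr(self, nm, np.zeros(n) if v is None else np.asarray(v, float))
        if self.obs_var is not None:
            self.obs_var = np.asarray(self.obs_var, float)

    @property
    def n_traits(self) -> int:
        return len(self.traits)


def _corr_to_cov(var, corr):
    var = np.asarray(var, float)
    sd = np.sqrt(var)
    return np.asarray(corr, float) * np.outer(sd, sd)


def default_morphology() -> TraitArchitecture:
    """Unit-phenotypic-variance morphology group: h2 = 0.4, moderate
    positive genetic correlations, observer effect on all three traits."""
    corr_g = np.array([[1.0, 0.5, 0.3], [0.5, 1.0, 0.4], [0.3, 0.4, 1.0]])
    return TraitArchitecture(
        traits=list(MORPH_TRAITS),
        G=_corr_to_cov([0.4, 0.4, 0.4], corr_g),
        PE=_corr_to_cov([0.15, 0.15, 0.15], np.eye(3) * 0.8 + 0.2),
        Y=_corr_to_cov([0.1, 0.1, 0.1], np.eye(3) * 0.7 + 0.3),
        R=_corr_to_cov([0.3, 0.3, 0.3], np.eye(3) * 0.9 + 0.1),
        obs_var=np.array([0.05, 0.05, 0.05]),
        group="morphology",
        intercept=np.array([19.0, 76.0, 18.0]),
        beta_age=np.array([0.05, 0.4, 0.1]),
        beta_age2=np.array([-0.01, -0.05, -0.02]),
        beta_sex=np.array([0.2, 1.5, 0.6]),
        beta_date=np.array([0.0, 0.01, 0.02]),
    )


def default_life_history() -> TraitArchitecture:
    """Life-history group (females only): lower heritability, strong
    clutch-fledging genetic correlation, no observer term."""
    corr_g = np.array([[1.0, -0.3, -0.2], [-0.3, 1.0, 0.7], [-0.2, 0.7, 1.0]])
    return TraitArchitecture(
        traits=list(LH_TRAITS),
        G=_corr_to_cov([0.25, 0.25, 0.25], corr_g),
        PE=_corr_to_cov([0.15, 0.15, 0.15], np.eye(3) * 0.8 + 0.2),
        Y=_corr_to_cov([0.2, 0.15, 0.15], np.eye(3) * 0.5 + 0.5),
        R=_corr_to_cov([0.4, 0.45, 0.45], np.eye(3) * 0.9 + 0.1),
        obs_var=None,
        group="life_history",
        intercept=np.array([105.0, 9.0, 6.0]),
        beta_age=np.array([-1.0, 0.3, 0.2]),
        beta_age2=np.array([0.15, -0.05, -0.04]),
    )


@dataclass
class StudyConfig:
    """Study-level simulation settings.

    delta is the climate-gradient alignment of the life-history G: 0 means
    one shared G everywhere; larger values drift G elements linearly along
    the synthetic climate PC1 axis (PSD-projected).
    """

    n_populations: int = 10
    n_founders: int = 200
    n_years: int = 25
    immigration_rate: float = 0.05     # immigrant founders per capita capacity, per year
    adult_survival: float = 0.5
    recruits_per_pair: float = 1.0
    carrying_capacity: int | None = None  # default: n_founders
    delta: float = 0.0                  # life-history G gradient
    delta_morph: float = 0.0
    n_observers: int = 8
    grid_shape: tuple = (40, 40)
    climate_corr_cells: float = 5.0
    groups: tuple = ("morphology", "life_history")
    morphology: TraitArchitecture = field(default_factory=default_morphology)
    life_history: TraitArchitecture = field(default_factory=default_life_history)
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.adult_survival < 1):
            raise ValueError("adult_survival must be in (0, 1)")
        if self.immigration_rate < 0 or self.recruits_per_pair <= 0:
            raise ValueError("rates out of range")
        if self.delta < 0 or self.delta_morph < 0:
            raise ValueError("delta must be >= 0")
        if self.carrying_capacity is None:
            self.carrying_capacity = self.n_founders

    def architecture(self, group: str) -> TraitArchitecture:
        return {"morphology": self.morphology, "life_history": self.life_history}[group]


@dataclass
class SyntheticStudy:
    """Full synthetic study with ground truth."""

    config: StudyConfig
    pedigrees: dict                     # population -> Pedigree
    sexes: dict                         # population -> ndarray ('M'/'F') aligned with ids
    breeding_values: dict               # (population, group) -> DataFrame
    phenotypes: dict                    # (population, group) -> DataFrame
    sites: pd.DataFrame                 # population, lon, lat, gradient score
    grid: ClimateGrid
    true_G: dict                        # (population, group) -> ndarray


class ExtinctionError(RuntimeError):
    pass


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def infer_sexes(ped: Pedigree, seed: int) -> np.ndarray:
    """Sexes consistent with pedigree roles (sires male, dams female);
    never-parents assigned at random."""
    sex = np.array([""] * ped.n, dtype=object)
    for s in ped.sire:
        if s != UNKNOWN:
            sex[s] = "M"
    for d in ped.dam:
        if d != UNKNOWN:
            sex[d] = "F"
    rng = _rng(seed)
    unassigned = np.where(sex == "")[0]
    sex[unassigned] = rng.choice(["M", "F"], size=len(unassigned))
    return sex.astype(str)


def simulate_pedigree(cfg: StudyConfig, population: str, seed: int) -> Pedigree:
    """Overlapping-generation pedigree with immigrant founders in any year.

    Founders enter in year 1; each subsequent year, surviving adults pair
    (monogamous, capped by carrying capacity), each pair recruits a
    Poisson number of offspring, immigrants arrive as extra founders, and
    adults survive with a fixed annual probability.
    """
    rng = _rng(seed)
    rows = []           # (id, sire, dam, cohort)
    alive: list = []    # (id, sex)
    counter = 0

    def new_ind(sire, dam, year):
        nonlocal counter
        counter += 1
        iid = f"{population}_{counter}"
        rows.append((iid, sire, dam, year))
        sex = "M" if rng.random() < 0.5 else "F"
        alive.append((iid, sex))
        return iid

    for _ in range(cfg.n_founders):
        new_ind("NA", "NA", 1)

    cap_pairs = max(1, cfg.carrying_capacity // 2)
    for year in range(2, cfg.n_years + 1):
        n_imm = rng.poisson(cfg.immigration_rate * cfg.carrying_capacity)
        for _ in range(n_imm):
            new_ind("NA", "NA", year)
        males = [i for i, s in alive if s == "M"]
        females = [i for i, s in alive if s == "F"]
        if not males or not females:
            raise ExtinctionError(
                f"population {population!r} lost one sex by year {year}; "
                "raise survival, fecundity, or founder count"
            )
        rng.shuffle(males)
        rng.shuffle(females)
        n_pairs = min(len(males), len(females), cap_pairs)
        snapshot_alive = list(alive)
        for sire, dam in zip(males[:n_pairs], females[:n_pairs]):
            for _ in range(rng.poisson(cfg.recruits_per_pair)):
                new_ind(sire, dam, year)
        # adult survival applies to the pre-breeding cohort; recruits enter next year
        survivors = [iw for iw in snapshot_alive if rng.random() < cfg.adult_survival]
        recruits = alive[len(snapshot_alive):]
        alive = survivors + recruits
        if not alive:
            raise ExtinctionError(
                f"population {population!r} went extinct in year {year}"
            )

    df = pd.DataFrame(rows, columns=["id", "sire", "dam", "cohort"])
    df["population"] = population
    return from_frame(df)


def simulate_breeding_values(
    ped: Pedigree, G: np.ndarray, F: np.ndarray, seed: int, traits=None
) -> pd.DataFrame:
    """Infinitesimal-model breeding values down a pedigree.

    Founders ~ N(0, G).  Non-founders: mean = average of known parents'
    values, covariance = G/2 * (1 - mean parental F); an unknown parent
    contributes zero mean and an extra G/4 so total variance stays G for
    outbred pedigrees.
    """
    G = _check_psd(G, "G")
    n_tr = G.shape[0]
    rng = _rng(seed)
    bv = np.zeros((ped.n, n_tr))
    if not np.allclose(G, 0):
        L = psd_sqrt(G)
        z = rng.standard_normal((ped.n, n_tr))
        for i in range(ped.n):
            s, d = ped.sire[i], ped.dam[i]
            if s == UNKNOWN and d == UNKNOWN:
                bv[i] = L @ z[i]
                continue
            mean = np.zeros(n_tr)
            fbar = 0.0
            extra = 0.0
            for p in (s, d):
                if p != UNKNOWN:
                    mean += 0.5 * bv[p]
                    fbar += 0.5 * F[p]
                else:
                    extra += 0.25
            seg = 0.5 * (1.0 - fbar) + extra
            bv[i] = mean + np.sqrt(seg) * (L @ z[i])
    cols = traits if traits is not None else [f"trait{k+1}" for k in range(n_tr)]
    out = pd.DataFrame(bv, columns=cols)
    out.insert(0, "id", ped.ids)
    return out


def _measurement_years(ped: Pedigree, rng, survival: float):
    """Reconstruct per-individual observation years: from first adult year
    until death (geometric lifespan), clipped to the monitored window."""
    last = int(ped.cohort.max())
    years = []
    for i in range(ped.n):
        c = int(ped.cohort[i])
        life = 1 + rng.geometric(1.0 - survival)
        y0 = c + 1
        y1 = min(c + life, last)
        years.append(list(range(y0, y1 + 1)))
    return years


def simulate_phenotypes(
    ped: Pedigree,
    bv: pd.DataFrame,
    arch: TraitArchitecture,
    seed: int,
    survival: float = 0.5,
    n_observers: int = 8,
    raw: bool = False,
) -> pd.DataFrame:
    """Phenotype records = fixed part + breeding value + PE + year (+
    observer, morphology) + residual.

    Morphological traits: both sexes, one record per observation year
    (repeated measures).  Life-history traits: females only, one clutch
    record per breeding year.  With ``raw=True`` the life-history table
    additionally contains second clutches and zero-fledging records so the
    upstream data filters have something to remove.
    """
    if list(bv.columns[1:]) != list(arch.traits):
        raise ValueError("breeding-value columns do not match architecture traits")
    rng = _rng(seed)
    n_tr = arch.n_traits
    sexes = infer_sexes(ped, int(rng.integers(2**31)))
    years_of = _measurement_years(ped, rng, survival)
    all_years = sorted({y for ys in years_of for y in ys}) or [1]
    ymap = {y: k for k, y in enumerate(all_years)}

    def _mvn(cov, size):
        return rng.standard_normal((size, n_tr)) @ psd_sqrt(cov).T

    pe = _mvn(arch.PE, ped.n)
    yr = _mvn(arch.Y, len(all_years))
    has_obs = arch.obs_var is not None
    if has_obs:
        ob = rng.standard_normal((n_observers, n_tr)) * np.sqrt(arch.obs_var)
    bvm = bv[arch.traits].to_numpy(float)
    pop = ped.population[0] if ped.population else "NA"

    recs = []
    for i in range(ped.n):
        if arch.group == "life_history" and sexes[i] != "F":
            continue
        for y in years_of[i]:
            age = y - int(ped.cohort[i])
            recs.append((i, y, age))
    if not recs:
        raise ValueError("no phenotype records generated (pedigree too small?)")
    recs = np.asarray(recs)
    nrec = len(recs)
    ind = recs[:, 0]
    year = recs[:, 1]
    age = recs[:, 2].astype(float)
    sex_num = (sexes[ind] == "M").astype(float)
    date = np.round(rng.normal(100.0, 10.0, size=nrec))
    observer = rng.integers(0, n_observers, size=nrec) if has_obs else np.full(nrec, -1)

    fixed = (
        arch.intercept[None, :]
        + np.outer(age, arch.beta_age)
        + np.outer(age**2, arch.beta_age2)
        + np.outer(sex_num, arch.beta_sex)
        + np.outer(date - 100.0, arch.beta_date)
    )
    resid = _mvn(arch.R, nrec)
    values = fixed + bvm[ind] + pe[ind] + yr[[ymap[y] for y in year]] + resid
    if has_obs:
        values = values + ob[observer]

    out = pd.DataFrame(values, columns=arch.traits)
    out.insert(0, "id", [ped.ids[k] for k in ind])
    out.insert(1, "population", pop)
    out.insert(2, "year", year)
    out.insert(3, "age", age)
    out.insert(4, "sex", sexes[ind])
    out.insert(5, "observer", [f"obs{o}" if o >= 0 else "NA" for o in observer])
    out.insert(6, "date", date)

    if raw and arch.group == "life_history":
        out.insert(7, "clutch_order", 1)
        # second clutches (later laying date) for ~15% of female-years
        second = out.sample(frac=0.15, random_state=int(rng.integers(2**31))).copy()
        second["laying_date"] = second["laying_date"] + rng.uniform(
            25, 45, size=len(second)
        )
        second["clutch_order"] = 2
        out = pd.concat([out, second], ignore_index=True)
        # occasional total breeding failure
        fail = rng.random(len(out)) < 0.05
        out.loc[fail, "fledging_success"] = 0.0
    return out


def simulate_climate_grid(cfg: StudyConfig, seed: int) -> ClimateGrid:
    """European-style temperature field on a lon/lat lattice.

    Three latent fields (a dominant south-north temperature level, a
    continentality/variability field, and a third nuisance field) are
    spatially smoothed and mixed through a fixed loading matrix into the
    eight temperature variables, giving strong inter-variable correlation
    and a dominant first PCA axis.  The distribution mask is a smooth
    suitability threshold.
    """
    ny, nx = cfg.grid_shape
    if nx <= 0 or ny <= 0:
        raise ValueError("grid dimensions must be positive")
    rng = _rng(seed)
    lon = np.linspace(-10.0, 30.0, nx)
    lat = np.linspace(35.0, 65.0, ny)
    LON, LAT = np.meshgrid(lon, lat)

    def smooth(f):
        if cfg.climate_corr_cells <= 0:
            return f
        g = ndimage.gaussian_filter(f, cfg.climate_corr_cells, mode="reflect")
        return (g - g.mean()) / (g.std() + 1e-12)

    lat01 = (LAT - LAT.mean()) / LAT.std()
    level = -1.2 * lat01 + 0.6 * smooth(rng.standard_normal((ny, nx)))
    variab = 0.8 * smooth(rng.standard_normal((ny, nx))) + 0.5 * (
        (LON - LON.mean()) / LON.std()
    )
    other = smooth(rng.standard_normal((ny, nx)))

    # rows = CLIMATE_VARS, cols = (level, variability, other)
    load = np.array(
        [
            [6.0, 0.3, 0.2],    # annual mean
            [0.5, 2.0, 0.3],    # diurnal range
            [-1.0, 3.5, 0.3],   # seasonality
            [5.0, 1.5, 0.3],    # max warmest month
            [6.5, -2.0, 0.3],   # min coldest month
            [-0.5, 3.8, 0.3],   # annual range
            [4.5, 1.0, 0.4],    # mean warmest quarter
            [6.0, -1.5, 0.4],   # mean coldest quarter
        ]
    )
    base = np.array([9.0, 8.0, 6.0, 24.0, -4.0, 28.0, 17.0, 1.0])
    lat01f, levf, varf, othf = (a.ravel() for a in (lat01, level, variab, other))
    latents = np.stack([levf, varf, othf], axis=1)
    X = base[None, :] + latents @ load.T
    X = X + rng.standard_normal(X.shape) * 0.3

    suit = smooth(rng.standard_normal((ny, nx))).ravel() - 0.8 * np.abs(lat01f) ** 2
    thr = np.quantile(suit, 0.35)
    mask = suit >= thr
    if mask.sum() < cfg.n_populations:
        raise ValueError("fewer masked cells than populations")

    cells = pd.DataFrame(X, columns=CLIMATE_VARS)
    cells.insert(0, "cell_id", np.arange(nx * ny))
    cells.insert(1, "lon", LON.ravel())
    cells.insert(2, "lat", LAT.ravel())
    cells.insert(3, "mask", mask)
    return ClimateGrid(cells)


def place_populations(
    grid: ClimateGrid,
    n_pops: int,
    seed: int,
    by: np.ndarray | None = None,
    secondary: np.ndarray | None = None,
) -> pd.DataFrame:
    """Put populations on masked cells spanning the climate gradient.

    Cells are ranked by ``by`` (default: annual mean temperature; the
    study generator passes the niche PC1 score) and sites are taken at
    even quantiles of that ranking, so populations run from one edge of
    the climatic niche to the other.  When a ``secondary`` coordinate is
    given (the PC2 score), each site is the cell nearest the median of
    that coordinate within its quantile band, emulating a transect along
    the dominant gradient.
    """
    rng = _rng(seed)
    masked = grid.masked.reset_index(drop=True)
    if by is not None:
        rank = np.argsort(np.asarray(by))
        order = masked.iloc[rank].reset_index(drop=True)
        sec = np.asarray(secondary)[rank] if secondary is not None else None
    else:
        order = masked.sort_values("t_annual_mean").reset_index(drop=True)
        sec = None
    qs = np.linspace(0.03, 0.97, n_pops)
    rows = []
    used = set()
    half_band = max(1, len(order) // (4 * n_pops))
    for k, q in enumerate(qs):
        j = int(round(q * (len(order) - 1)))
        if sec is not None:
            lo = max(0, j - half_band)
            hi = min(len(order), j + half_band + 1)
            band = [i for i in range(lo, hi) if i not in used]
            if band:
                med = np.median(sec)
                j = band[int(np.argmin(np.abs(sec[band] - med)))]
        while j in used:
            j = (j + 1) % len(order)
        used.add(j)
        c = order.iloc[j]
        rows.append((f"pop{k+1}", float(c["lon"]), float(c["lat"])))
    sites = pd.DataFrame(rows, columns=["population", "lon", "lat"])
    # small jitter so no two sites coincide exactly
    sites["lon"] += rng.uniform(-0.05, 0.05, size=n_pops)
    sites["lat"] += rng.uniform(-0.05, 0.05, size=n_pops)
    return sites


def _gradient_g(arch: TraitArchitecture, delta: float, z: float) -> np.ndarray:
    """True G for a population with (centered, scaled) gradient score z.

    The gradient acts on the axes a field study would report: it inflates
    variance along the leading eigenvector and along the first trait (the
    laying-date analogue), and it rotates the matrix in the plane spanned
    by those two axes, so size, shape, and orientation all drift with z.
    PSD-projected.
    """
    if delta == 0:
        return arch.G.copy()
    n = arch.n_traits
    w, V = np.linalg.eigh(arch.G)
    v1 = V[:, -1]
    e = np.zeros(n)
    e[0] = 1.0
    # log-linear variance drift keeps G positive definite at the cold end
    # instead of clipping it flat
    g = np.expm1(0.45 * delta * z)
    D = w[-1] * np.outer(v1, v1) + arch.G[0, 0] * np.outer(e, e)
    M = _psd_project(arch.G + g * D, floor=1e-4 * np.trace(arch.G))
    # orientation drift: rotate g_max toward/away from the first trait axis
    u = e - np.dot(e, v1) * v1
    nu = np.linalg.norm(u)
    if nu > 1e-8:
        u = u / nu
        # saturating rotation: pairwise g_max angles stay monotone in the
        # gradient gap and never exceed 90 degrees
        theta = (np.pi / 4) * np.tanh(delta * z)
        P = np.outer(v1, v1) + np.outer(u, u)
        Q = (
            np.eye(n)
            - P
            + np.cos(theta) * P
            + np.sin(theta) * (np.outer(u, v1) - np.outer(v1, u))
        )
        M = Q @ M @ Q.T
    return 0.5 * (M + M.T)


def simulate_study(cfg: StudyConfig) -> SyntheticStudy:
    """Wire pedigrees, breeding values, phenotypes, and climate into one
    coherent multi-population study with stored ground truth."""
    from .niche import fit_niche_pca, project_populations

    ss = np.random.SeedSequence(cfg.seed)
    seeds = ss.spawn(3 + 4 * cfg.n_populations)
    grid = simulate_climate_grid(cfg, seeds[0])
    space = fit_niche_pca(grid)
    sites = place_populations(
        grid,
        cfg.n_populations,
        seeds[1],
        by=space.cell_scores["pc1"].to_numpy(),
        secondary=space.cell_scores["pc2"].to_numpy(),
    )
    proj = project_populations(space, sites, grid)
    z = proj.table["pc1"].to_numpy()
    zc = (z - z.mean()) / (np.abs(z - z.mean()).max() + 1e-12)
    sites = sites.copy()
    sites["gradient"] = zc

    pedigrees, sexes, bvs, phens, trueG = {}, {}, {}, {}, {}
    for k in range(cfg.n_populations):
        pop = sites["population"].iloc[k]
        sk = seeds[3 + 4 * k : 3 + 4 * (k + 1)]
        ped = simulate_pedigree(cfg, pop, sk[0])
        F = inbreeding(ped)
        pedigrees[pop] = ped
        sexes[pop] = infer_sexes(ped, int(np.random.default_rng(sk[1]).integers(2**31)))
        for g, group in enumerate(cfg.groups):
            arch = cfg.architecture(group)
            delta = cfg.delta if group == "life_history" else cfg.delta_morph
            Gp = _gradient_g(arch, delta, zc[k])
            trueG[(pop, group)] = Gp
            child = np.random.SeedSequence(
                entropy=sk[2].entropy, spawn_key=sk[2].spawn_key + (g,)
            )
            bv = simulate_breeding_values(ped, Gp, F, child, traits=arch.traits)
            bvs[(pop, group)] = bv
            child2 = np.random.SeedSequence(
                entropy=sk[3].entropy, spawn_key=sk[3].spawn_key + (g,)
            )
            phens[(pop, group)] = simulate_phenotypes(
                ped,
                bv,
                arch,
                child2,
                survival=cfg.adult_survival,
                n_observers=cfg.n_observers,
            )
    return SyntheticStudy(
        config=cfg,
        pedigrees=pedigrees,
        sexes=sexes,
        breeding_values=bvs,
        phenotypes=phens,
        sites=sites,
        grid=grid,
        true_G=trueG,
    )
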