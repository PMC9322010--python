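"""Synthetic metacommunity generator with known decay structure.

Sites are scattered over a square region, environmental variables are
spatially autocorrelated Gaussian fields, and species respond to the
environment through Gaussian niches around per-species optima while an
exponential dispersal kernel around a species' home range limits its spatial
reach.  Traits are drawn from the niche optima (``trait_env_coupling = 1``,
full environmental filtering of traits) through to independent values
(``coupling = 0``); ``functional_redundancy`` assigns shared trait profiles
to groups of species so that taxonomic turnover can occur with little or no
functional turnover.  Every stage is deterministic given the seed, and the
generated bundles pass the standard inclusion rules at default sizes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .dataset import CommunityDataset, DatasetMeta, drop_empty

log = logging.getLogger(__name__)

KM_PER_DEGREE = 111.32


@dataclass
class SimulationParams:
    n_sites: int = 20
    n_species: int = 40
    n_traits: int = 4
    n_env_vars: int = 3
    extent_km: float = 200.0
    env_spatial_autocorr: float = 100.0   # range (km) of the exponential covariance
    niche_breadth: float = 1.5            # SD of the Gaussian niche in env z-units
    dispersal_range_km: float = 150.0     # e-folding range of the dispersal kernel
    trait_env_coupling: float = 0.5       # 0 = traits random w.r.t. environment
    functional_redundancy: float = 0.0    # fraction of species sharing trait profiles
    noise_sd: float = 0.3                 # lognormal abundance noise (log scale)
    individuals_per_site: int = 100
    centre_lat: float = 45.0
    centre_lon: float = 10.0
    realm: str = "terrestrial"
    biotic_group: str = "simulated"
    body_size_log10_g: float = 0.0
    dispersal_mode: str = "active"
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.trait_env_coupling <= 1.0):
            raise ValueError("trait_env_coupling must lie in [0, 1]")
        if not (0.0 <= self.functional_redundancy <= 1.0):
            raise ValueError("functional_redundancy must lie in [0, 1]")
        for name in ("n_sites", "n_species", "n_traits", "n_env_vars",
                     "extent_km", "niche_breadth", "dispersal_range_km",
                     "individuals_per_site"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _gp_fields(xy_km: np.ndarray, n_fields: int, range_km: float, rng) -> np.ndarray:
    """Spatially autocorrelated standard-normal fields via an exact GP draw
    (exponential covariance); site counts are small enough for a Cholesky."""
    D = squareform(pdist(xy_km))
    C = np.exp(-D / max(range_km, 1e-9)) + 1e-8 * np.eye(len(xy_km))
    L = np.linalg.cholesky(C)
    return (L @ rng.standard_normal((len(xy_km), n_fields)))


def _simulate_once(p: SimulationParams, rng) -> CommunityDataset:
    side = p.extent_km / math.sqrt(2.0)
    xy = rng.uniform(0.0, side, size=(p.n_sites, 2))

    env = _gp_fields(xy, p.n_env_vars, p.env_spatial_autocorr, rng)

    # Gaussian niches over the environmental fields
    optima = rng.uniform(-2.0, 2.0, size=(p.n_species, p.n_env_vars))
    dev = env[:, None, :] - optima[None, :, :]          # sites x species x env
    niche = np.exp(-np.sum(dev**2, axis=2) / (2.0 * p.niche_breadth**2))

    # exponential dispersal kernel around a per-species home centre
    homes = rng.uniform(0.0, side, size=(p.n_species, 2))
    d_home = np.sqrt(((xy[:, None, :] - homes[None, :, :]) ** 2).sum(axis=2))
    kernel = np.exp(-d_home / p.dispersal_range_km)

    raw = niche * kernel * rng.lognormal(0.0, p.noise_sd, size=niche.shape)
    lam = p.individuals_per_site * raw / raw.sum(axis=1, keepdims=True)
    counts = rng.poisson(lam).astype(float)

    # traits: profiles shared within redundancy groups; values mix an
    # environmental signal (projection of the group's niche optima) with noise
    n_profiles = max(1, round(p.n_species * (1.0 - p.functional_redundancy)))
    profile_of = np.arange(p.n_species) % n_profiles
    proj = rng.standard_normal((p.n_env_vars, p.n_traits))
    proj /= np.linalg.norm(proj, axis=0, keepdims=True)
    profile_optima = optima[:n_profiles]
    signal = profile_optima @ proj                      # profiles x traits
    noise = rng.standard_normal((n_profiles, p.n_traits))
    profiles = p.trait_env_coupling * signal + (1.0 - p.trait_env_coupling) * noise
    traits = profiles[profile_of]

    lat = p.centre_lat + (xy[:, 1] - side / 2.0) / KM_PER_DEGREE
    lon = p.centre_lon + (xy[:, 0] - side / 2.0) / (
        KM_PER_DEGREE * math.cos(math.radians(p.centre_lat))
    )

    sites = [f"site_{i + 1:03d}" for i in range(p.n_sites)]
    species = [f"sp_{s + 1:03d}" for s in range(p.n_species)]
    ds = CommunityDataset(
        abundance=pd.DataFrame(counts, index=sites, columns=species),
        traits=pd.DataFrame(
            traits, index=species, columns=[f"trait_{t + 1}" for t in range(p.n_traits)]
        ),
        coords=pd.DataFrame({"latitude": lat, "longitude": lon}, index=sites),
        env=pd.DataFrame(
            env, index=sites, columns=[f"env_{v + 1}" for v in range(p.n_env_vars)]
        ),
        meta=DatasetMeta(
            realm=p.realm,
            biotic_group=p.biotic_group,
            body_size_log10_g=p.body_size_log10_g,
            dispersal_mode=p.dispersal_mode,
        ),
        name=f"sim_seed{p.seed}",
    )
    return drop_empty(ds)


def simulate_dataset(params: SimulationParams, max_attempts: int = 10) -> CommunityDataset:
    """Generate one four-table dataset; resamples (with a warning) if a draw
    leaves empty sites or falls below the inclusion rules."""
    ss = np.random.SeedSequence(params.seed)
    for attempt, child in enumerate(ss.spawn(max_attempts)):
        rng = np.random.default_rng(child)
        ds = _simulate_once(params, rng)
        occ = ds.abundance.to_numpy() > 0
        if ds.n_sites == params.n_sites and occ.any(axis=1).all():
            return ds
        log.warning("simulation attempt %d produced empty sites; resampling", attempt + 1)
    raise RuntimeError(f"could not generate a valid dataset in {max_attempts} attempts")


def simulate_decay_pairs(
    intercept: float,
    slope: float,
    n_pairs: int,
    dispersion: float = 0.0,
    seed: int = 0,
    d_max: float | None = None,
):
    """Direct test harness for the decay GLM: draws distances uniformly on
    [0, d_max] and similarities with mean exp(intercept + slope * d) and
    quasi-binomial-style variance dispersion * mu * (1 - mu) (a beta draw),
    clamped to [0, 1]."""
    if math.exp(intercept) > 1.0 + 1e-12:
        raise ValueError("exp(intercept) must be <= 1")
    if d_max is None:
        d_max = 3.0 / abs(slope) if slope < 0 else 1.0
    rng = np.random.default_rng(seed)
    d = rng.uniform(0.0, d_max, size=n_pairs)
    mu = np.exp(intercept + slope * d)
    if np.any(mu >= 1.0) or np.any(mu <= 0.0):
        raise ValueError("mean similarity outside (0, 1) over the distance range")
    if dispersion <= 1e-12:
        s = mu.copy()
    else:
        if dispersion >= 1.0:
            raise ValueError("dispersion must be < 1 for the beta noise model")
        nu = 1.0 / dispersion - 1.0
        s = rng.beta(mu * nu, (1.0 - mu) * nu)
    return np.clip(s, 0.0, 1.0), d


def default_param_sampler(rng) -> SimulationParams:
    """Dataset-to-dataset variation used by :func:`simulate_collection`:
    spatial extent, dispersal range, latitude, realm and organismal metadata
    all vary so the cross-dataset meta-analysis has structure to find."""
    extent = float(np.exp(rng.uniform(np.log(50.0), np.log(2000.0))))
    return SimulationParams(
        n_sites=int(rng.integers(12, 25)),
        n_species=int(rng.integers(25, 50)),
        extent_km=extent,
        env_spatial_autocorr=extent * 0.5,
        dispersal_range_km=float(extent * np.exp(rng.uniform(np.log(0.2), np.log(2.0)))),
        trait_env_coupling=float(rng.uniform(0.0, 1.0)),
        functional_redundancy=float(rng.uniform(0.0, 0.6)),
        centre_lat=float(rng.uniform(0.0, 70.0)),
        centre_lon=float(rng.uniform(-30.0, 30.0)),
        realm=str(rng.choice(["freshwater", "marine", "terrestrial"])),
        body_size_log10_g=float(rng.uniform(-6.0, 6.0)),
        dispersal_mode=str(rng.choice(["active", "passive", "seed"])),
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def simulate_collection(n_datasets: int, param_sampler=None, seed: int = 0):
    """Generate a collection of datasets plus a truth table of the parameters
    each one was built from.  Returns ``(datasets, truth_table)``."""
    sampler = param_sampler or default_param_sampler
    rng = np.random.default_rng(seed)
    datasets, rows = [], []
    for i in range(n_datasets):
        p = sampler(rng)
        ds = simulate_dataset(p)
        ds.name = f"sim_{i + 1:03d}"
        datasets.append(ds)
        row = asdict(p)
        row["dataset"] = ds.name
        rows.append(row)
    truth = pd.DataFrame(rows).set_index("dataset")
    return datasets, truth
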