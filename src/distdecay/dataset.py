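"""Four-table community dataset bundle: containers, I/O, and curation filters.

A dataset couples a sites-by-species abundance matrix with a species-by-traits
table, site coordinates (decimal-degree WGS84) and site-level environmental
variables, plus house metadata (realm, biotic group, body size, dispersal
mode).  All downstream similarity / decay machinery consumes this bundle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger(__name__)

REALMS = ("freshwater", "marine", "terrestrial")
DISPERSAL_MODES = ("active", "passive", "seed")
TRAIT_TYPES = ("continuous", "binary", "categorical", "fuzzy")

_TABLE_NAMES = ("abundance", "traits", "coords", "env")


class DatasetError(ValueError):
    """Fatal problem with a dataset bundle (missing table, label mismatch...)."""


@dataclass
class DatasetMeta:
    realm: str = "terrestrial"
    biotic_group: str = "unspecified"
    body_size_log10_g: float = float("nan")
    dispersal_mode: str = "active"
    occurrence_only: bool = False

    def __post_init__(self):
        if self.realm not in REALMS:
            raise DatasetError(f"unknown realm {self.realm!r}; expected one of {REALMS}")
        if self.dispersal_mode not in DISPERSAL_MODES:
            raise DatasetError(
                f"unknown dispersal mode {self.dispersal_mode!r}; expected one of {DISPERSAL_MODES}"
            )


@dataclass
class CommunityDataset:
    """The unit of analysis: four linked tables plus metadata.

    ``trait_types`` maps each trait column to its declared type; columns of a
    fuzzy-coded group are listed under their group name in ``fuzzy_groups``
    and the whole group counts as a single trait.
    """

    abundance: pd.DataFrame
    traits: pd.DataFrame
    coords: pd.DataFrame
    env: pd.DataFrame
    meta: DatasetMeta = field(default_factory=DatasetMeta)
    trait_types: dict = field(default_factory=dict)
    fuzzy_groups: dict = field(default_factory=dict)
    name: str = "dataset"

    def __post_init__(self):
        self._check_labels()
        if (self.abundance.to_numpy(dtype=float) < 0).any():
            raise DatasetError("negative abundances")
        lat = self.coords.iloc[:, 0].to_numpy(dtype=float)
        lon = self.coords.iloc[:, 1].to_numpy(dtype=float)
        if np.any((lat < -90) | (lat > 90)):
            bad = list(self.coords.index[(lat < -90) | (lat > 90)])
            raise DatasetError(f"latitude out of [-90, 90] for sites {bad}")
        if np.any((lon < -180) | (lon > 180)):
            bad = list(self.coords.index[(lon < -180) | (lon > 180)])
            raise DatasetError(f"longitude out of [-180, 180] for sites {bad}")
        if not self.trait_types:
            self.trait_types = infer_trait_types(self.traits, self.fuzzy_groups)

    def _check_labels(self):
        sites = list(self.abundance.index)
        for tbl_name, tbl in (("coords", self.coords), ("env", self.env)):
            if list(tbl.index) != sites:
                missing = sorted(set(sites) ^ set(tbl.index))
                raise DatasetError(
                    f"site labels of {tbl_name} do not match abundance; differing labels: {missing}"
                )
        if list(self.traits.index) != list(self.abundance.columns):
            missing = sorted(set(self.traits.index) ^ set(self.abundance.columns))
            raise DatasetError(
                f"species labels of traits do not match abundance columns; differing labels: {missing}"
            )

    # -- convenience -------------------------------------------------------
    @property
    def n_sites(self) -> int:
        return self.abundance.shape[0]

    @property
    def n_species(self) -> int:
        return self.abundance.shape[1]

    @property
    def n_env(self) -> int:
        return self.env.shape[1]

    @property
    def n_traits(self) -> int:
        """Number of traits, a fuzzy group counting as one."""
        fuzzy_cols = {c for cols in self.fuzzy_groups.values() for c in cols}
        plain = [c for c in self.traits.columns if c not in fuzzy_cols]
        return len(plain) + len(self.fuzzy_groups)

    @property
    def site_ids(self):
        return list(self.abundance.index)

    @property
    def species_ids(self):
        return list(self.abundance.columns)

    def copy(self) -> "CommunityDataset":
        return replace(
            self,
            abundance=self.abundance.copy(),
            traits=self.traits.copy(),
            coords=self.coords.copy(),
            env=self.env.copy(),
            trait_types=dict(self.trait_types),
            fuzzy_groups={k: list(v) for k, v in self.fuzzy_groups.items()},
        )


@dataclass
class ValidationReport:
    passed: bool
    n_sites: int
    n_species: int
    n_traits: int
    n_env: int
    messages: list

    def to_dict(self) -> dict:
        return {
            "passed": bool(self.passed),
            "n_sites": int(self.n_sites),
            "n_species": int(self.n_species),
            "n_traits": int(self.n_traits),
            "n_env": int(self.n_env),
            "messages": list(self.messages),
        }


def infer_trait_types(traits: pd.DataFrame, fuzzy_groups: dict | None = None) -> dict:
    """Heuristic trait typing used when a schema does not declare types."""
    fuzzy_cols = {c for cols in (fuzzy_groups or {}).values() for c in cols}
    types = {}
    for col in traits.columns:
        if col in fuzzy_cols:
            types[col] = "fuzzy"
            continue
        s = traits[col]
        if not pd.api.types.is_numeric_dtype(s):
            types[col] = "categorical"
        elif set(s.dropna().unique()) <= {0, 1}:
            types[col] = "binary"
        else:
            types[col] = "continuous"
    return types


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _read_table(path: Path) -> pd.DataFrame:
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    return pd.read_csv(path, sep=sep, index_col=0)


def _find_table(bundle: Path, name: str) -> Path | None:
    for ext in (".csv", ".tsv", ".tab"):
        p = bundle / f"{name}{ext}"
        if p.exists():
            return p
    return None


def load_dataset(bundle_path, schema: dict | None = None) -> CommunityDataset:
    """Load a four-table bundle directory into a :class:`CommunityDataset`.

    The bundle holds ``abundance``, ``traits``, ``coords`` and ``env`` tables
    (CSV or TSV, first column = labels) and optionally a ``schema.yaml`` with
    trait types, fuzzy groups and metadata.  An explicit ``schema`` dict
    overrides the file.
    """
    bundle = Path(bundle_path)
    if not bundle.is_dir():
        raise DatasetError(f"bundle path {bundle} is not a directory")

    tables = {}
    for name in _TABLE_NAMES:
        p = _find_table(bundle, name)
        if p is None:
            raise DatasetError(f"missing table {name!r} in bundle {bundle}")
        tables[name] = _read_table(p)

    if schema is None:
        schema_path = bundle / "schema.yaml"
        schema = yaml.safe_load(schema_path.read_text()) if schema_path.exists() else {}
    schema = schema or {}

    meta = DatasetMeta(**schema.get("meta", {}))
    return CommunityDataset(
        abundance=tables["abundance"].astype(float),
        traits=tables["traits"],
        coords=tables["coords"].astype(float),
        env=tables["env"].astype(float),
        meta=meta,
        trait_types=dict(schema.get("trait_types", {})),
        fuzzy_groups={k: list(v) for k, v in schema.get("fuzzy_groups", {}).items()},
        name=schema.get("name", bundle.name),
    )


def write_dataset(ds: CommunityDataset, bundle_path, float_format: str = "%.10g") -> Path:
    """Write the bundle back to delimited text; round-trips with load_dataset."""
    bundle = Path(bundle_path)
    bundle.mkdir(parents=True, exist_ok=True)
    ds.abundance.to_csv(bundle / "abundance.csv", float_format=float_format)
    ds.traits.to_csv(bundle / "traits.csv", float_format=float_format)
    ds.coords.to_csv(bundle / "coords.csv", float_format=float_format)
    ds.env.to_csv(bundle / "env.csv", float_format=float_format)
    schema = {
        "name": ds.name,
        "trait_types": dict(ds.trait_types),
        "fuzzy_groups": {k: list(v) for k, v in ds.fuzzy_groups.items()},
        "meta": {
            "realm": ds.meta.realm,
            "biotic_group": ds.meta.biotic_group,
            "body_size_log10_g": float(ds.meta.body_size_log10_g),
            "dispersal_mode": ds.meta.dispersal_mode,
            "occurrence_only": bool(ds.meta.occurrence_only),
        },
    }
    (bundle / "schema.yaml").write_text(yaml.safe_dump(schema))
    return bundle


# ---------------------------------------------------------------------------
# Curation
# ---------------------------------------------------------------------------

def validate_dataset(
    ds: CommunityDataset,
    min_sites: int = 10,
    min_env: int = 2,
    min_traits: int = 3,
) -> ValidationReport:
    """Inclusion rules: at least 10 sites, 2 environmental variables and 3
    traits (a fuzzy-coded group counts as one trait)."""
    messages = []
    if ds.n_sites < min_sites:
        messages.append(f"only {ds.n_sites} sites; need >= {min_sites}")
    if ds.n_env < min_env:
        messages.append(f"only {ds.n_env} environmental variables; need >= {min_env}")
    if ds.n_traits < min_traits:
        messages.append(f"only {ds.n_traits} traits; need >= {min_traits}")
    return ValidationReport(
        passed=not messages,
        n_sites=ds.n_sites,
        n_species=ds.n_species,
        n_traits=ds.n_traits,
        n_env=ds.n_env,
        messages=messages,
    )


def filter_env_variables(ds: CommunityDataset, max_missing: float = 0.05) -> CommunityDataset:
    """Keep continuous env variables with a missing fraction strictly below
    ``max_missing``; mean-impute the surviving cells.  Returns a new dataset."""
    env = ds.env
    keep = []
    for col in env.columns:
        if not pd.api.types.is_numeric_dtype(env[col]):
            log.info("env variable %r dropped: not continuous", col)
            continue
        frac = env[col].isna().mean()
        if frac >= max_missing:
            log.info("env variable %r dropped: %.1f%% missing", col, 100 * frac)
            continue
        keep.append(col)
    if not keep:
        raise DatasetError("no environmental variables survive curation")
    new_env = env[keep].astype(float).copy()
    for col in keep:
        n_missing = int(new_env[col].isna().sum())
        if n_missing:
            log.info("env variable %r: imputing %d missing cells by column mean", col, n_missing)
            new_env[col] = new_env[col].fillna(new_env[col].mean())
    out = ds.copy()
    out.env = new_env
    return out


def to_occurrence(ds: CommunityDataset) -> CommunityDataset:
    """Replace abundances by 0/1 presence; idempotent."""
    out = ds.copy()
    out.abundance = (ds.abundance > 0).astype(float)
    return out


def drop_empty(ds: CommunityDataset) -> CommunityDataset:
    """Remove all-zero species columns and empty sites so that every species
    occurs somewhere and every site holds at least one species."""
    occ = ds.abundance.to_numpy(dtype=float) > 0
    keep_sites = occ.any(axis=1)
    keep_species = occ.any(axis=0)
    out = ds.copy()
    out.abundance = ds.abundance.loc[keep_sites, keep_species]
    out.coords = ds.coords.loc[keep_sites]
    out.env = ds.env.loc[keep_sites]
    out.traits = ds.traits.loc[keep_species]
    out.trait_types = dict(ds.trait_types)
    return out
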