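"""Pairwise community similarity (Sorensen family) and its decomposition.

Similarity between communities j and k is built from shared (a) and unique
(b, c) features:

    S_jk = 1 - (b + c) / (2a + b + c)

For taxonomic similarity a feature is a species (counts for occurrence data,
min/remainder sums for abundances); for functional similarity the features
are the shared and unique volumes of the two communities' trait-space
hypervolumes.  Total dissimilarity splits exactly into a replacement
(turnover) part and a richness-difference part:

    beta_total = (b + c) / (2a + b + c)
    beta_repl  = 2 min(b, c) / (2a + b + c)
    beta_rich  = |b - c| / (2a + b + c)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .dataset import CommunityDataset
from .traitspace import (
    TraitSpace,
    build_hypervolume,
    build_trait_space,
    hypervolume_overlap,
)

log = logging.getLogger(__name__)


class SimilarityComponents(NamedTuple):
    a: float
    b: float
    c: float


def sorensen_components_occurrence(x_j, x_k) -> SimilarityComponents:
    """Counts of shared and unique species from two presence vectors."""
    pj = np.asarray(x_j) > 0
    pk = np.asarray(x_k) > 0
    if pj.shape != pk.shape:
        raise ValueError("communities must share the same species universe")
    if not pj.any() and not pk.any():
        raise ValueError("both communities are empty")
    a = float(np.sum(pj & pk))
    b = float(np.sum(pj & ~pk))
    c = float(np.sum(~pj & pk))
    return SimilarityComponents(a, b, c)


def sorensen_components_abundance(x_j, x_k) -> SimilarityComponents:
    """Min/remainder (Bray-Curtis-family) generalisation to abundances:
    a = sum min, b and c the abundance unique to each community."""
    xj = np.asarray(x_j, dtype=float)
    xk = np.asarray(x_k, dtype=float)
    if (xj < 0).any() or (xk < 0).any():
        raise ValueError("negative abundance")
    if xj.sum() == 0 and xk.sum() == 0:
        raise ValueError("both communities are empty")
    mins = np.minimum(xj, xk)
    return SimilarityComponents(float(mins.sum()), float((xj - mins).sum()), float((xk - mins).sum()))


def similarity_from_components(comp: SimilarityComponents) -> float:
    a, b, c = comp
    denom = 2 * a + b + c
    if denom <= 0:
        raise ValueError("a = b = c = 0: similarity undefined")
    return 1.0 - (b + c) / denom


def partition_dissimilarity(comp: SimilarityComponents):
    """(beta_total, beta_repl, beta_rich); repl + rich == total exactly."""
    a, b, c = comp
    denom = 2 * a + b + c
    if denom <= 0:
        raise ValueError("a = b = c = 0: dissimilarity undefined")
    beta_total = (b + c) / denom
    beta_repl = 2 * min(b, c) / denom
    beta_rich = abs(b - c) / denom
    return beta_total, beta_repl, beta_rich


# ---------------------------------------------------------------------------
# Matrices
# ---------------------------------------------------------------------------

@dataclass
class PairwiseSimilarity:
    """Condensed site-pair similarity container (i < j ordering, upper
    triangle of the square matrix read row-wise, as in scipy.squareform)."""

    labels: list
    mode: str                    # occurrence | abundance
    facet: str                   # taxonomic | functional
    S_total: np.ndarray          # condensed, in [0,1]; NaN where a pair is excluded
    beta_total: np.ndarray
    beta_repl: np.ndarray
    beta_rich: np.ndarray
    components: np.ndarray       # n_pairs x 3 (a, b, c)
    excluded_sites: list = field(default_factory=list)

    @property
    def n_sites(self) -> int:
        return len(self.labels)

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.S_total)

    def to_square(self, which: str = "S_total") -> pd.DataFrame:
        from scipy.spatial.distance import squareform

        vec = getattr(self, which)
        sq = squareform(np.nan_to_num(vec), checks=False)
        sq[np.isnan(squareform(vec, checks=False))] = np.nan
        if which == "S_total":
            np.fill_diagonal(sq, 1.0)
        return pd.DataFrame(sq, index=self.labels, columns=self.labels)

    def to_frame(self) -> pd.DataFrame:
        """Long format: one row per site pair."""
        ii, jj = np.triu_indices(self.n_sites, k=1)
        return pd.DataFrame(
            {
                "site_i": [self.labels[i] for i in ii],
                "site_j": [self.labels[j] for j in jj],
                "facet": self.facet,
                "mode": self.mode,
                "S_total": self.S_total,
                "beta_total": self.beta_total,
                "beta_repl": self.beta_repl,
                "beta_rich": self.beta_rich,
                "a": self.components[:, 0],
                "b": self.components[:, 1],
                "c": self.components[:, 2],
            }
        )


def _from_component_array(labels, comps: np.ndarray, mode: str, facet: str, excluded=None) -> PairwiseSimilarity:
    n_pairs = comps.shape[0]
    S = np.full(n_pairs, np.nan)
    bt = np.full(n_pairs, np.nan)
    br = np.full(n_pairs, np.nan)
    bd = np.full(n_pairs, np.nan)
    for p in range(n_pairs):
        a, b, c = comps[p]
        if not np.isfinite(a):
            continue
        denom = 2 * a + b + c
        if denom <= 0:
            continue
        S[p] = 1.0 - (b + c) / denom
        bt[p] = (b + c) / denom
        br[p] = 2 * min(b, c) / denom
        bd[p] = abs(b - c) / denom
    return PairwiseSimilarity(
        labels=list(labels),
        mode=mode,
        facet=facet,
        S_total=S,
        beta_total=bt,
        beta_repl=br,
        beta_rich=bd,
        components=comps,
        excluded_sites=list(excluded or []),
    )


def taxonomic_similarity_matrix(ds: CommunityDataset, mode: str = "occurrence") -> PairwiseSimilarity:
    """All-pairs taxonomic similarity from the sites-by-species matrix."""
    if mode not in ("occurrence", "abundance"):
        raise ValueError(f"unknown mode {mode!r}")
    X = ds.abundance.to_numpy(dtype=float)
    if mode == "occurrence" or ds.meta.occurrence_only:
        X = (X > 0).astype(float)
    n = X.shape[0]
    ii, jj = np.triu_indices(n, k=1)
    mins = np.minimum(X[ii], X[jj])
    a = mins.sum(axis=1)
    b = (X[ii] - mins).sum(axis=1)
    c = (X[jj] - mins).sum(axis=1)
    comps = np.column_stack([a, b, c])
    return _from_component_array(ds.site_ids, comps, mode, "taxonomic")


def functional_similarity_matrix(
    ds: CommunityDataset,
    mode: str = "occurrence",
    seed: int = 0,
    space: TraitSpace | None = None,
    n_samples: int = 2000,
    q: float = 0.95,
    min_species: int = 4,
    species_permutation: np.ndarray | None = None,
) -> PairwiseSimilarity:
    """All-pairs functional similarity from hypervolume overlaps.

    Builds (or reuses) the dataset's trait space, constructs one hypervolume
    per site from the coordinates of its member species (abundance-weighted
    in abundance mode) and converts shared/unique overlap volumes to the
    Sorensen similarity and its partition.  Sites with fewer than
    ``min_species`` members are excluded (their pairs are NaN).

    ``species_permutation`` reassigns species to trait-space coordinates
    (row ``s`` of the community matrix takes the coordinates of species
    ``perm[s]``) — the fast path for trait-shuffling null models, exactly
    equivalent to rebuilding Gower + PCoA on a row-shuffled trait table.
    """
    if space is None:
        space = build_trait_space(ds.traits, ds.trait_types, ds.fuzzy_groups)
    X = ds.abundance.to_numpy(dtype=float)
    if mode == "occurrence" or ds.meta.occurrence_only:
        X = (X > 0).astype(float)
    n = X.shape[0]
    coords = space.coordinates
    if species_permutation is not None:
        coords = coords[np.asarray(species_permutation)]

    ss = np.random.SeedSequence(seed)
    hv_seeds = ss.spawn(n + 1)
    pair_ss = hv_seeds[-1]

    hvs, excluded = [], []
    for i in range(n):
        members = np.flatnonzero(X[i] > 0)
        if len(members) < min_species:
            hvs.append(None)
            excluded.append(ds.site_ids[i])
            continue
        w = X[i, members] if mode == "abundance" else None
        hv = build_hypervolume(
            space,
            coords[members],
            weights=w,
            seed=hv_seeds[i].generate_state(1)[0] % (2**31),
            n_samples=n_samples,
            q=q,
            min_species=min_species,
        )
        hvs.append(hv)
    if excluded:
        log.warning(
            "%d sites excluded from functional analyses (< %d species): %s",
            len(excluded), min_species, excluded,
        )
    if all(h is None for h in hvs):
        raise ValueError("all sites excluded from functional analyses")

    ii, jj = np.triu_indices(n, k=1)
    pair_seeds = pair_ss.spawn(len(ii))
    comps = np.full((len(ii), 3), np.nan)
    for p, (i, j) in enumerate(zip(ii, jj)):
        if hvs[i] is None or hvs[j] is None:
            continue
        comps[p] = hypervolume_overlap(
            hvs[i], hvs[j], seed=pair_seeds[p].generate_state(1)[0] % (2**31)
        )
    out = _from_component_array(ds.site_ids, comps, mode, "functional", excluded)
    out._hypervolumes = hvs  # cached for gamma-diversity computations
    return out
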