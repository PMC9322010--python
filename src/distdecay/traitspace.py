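"""Functional trait space: balanced Gower distances, PCoA embedding, and
probabilistic (Gaussian-kernel) hypervolumes with Monte-Carlo set operations.

The trait space of a dataset is built once: mixed-type trait columns are
combined into a [0,1] Gower distance with trait weights balanced so every
trait contributes equally on average, the distance matrix is embedded into
three principal-coordinate axes, and each community is represented as the
region of that space where a Gaussian mixture centred on its member species
exceeds a density threshold enclosing 95% of the mixture mass.  Volumes are
expressed in units of the embedding axes cubed (SD^3).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import eigh

log = logging.getLogger(__name__)


class TraitSpaceError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Balanced Gower distance
# ---------------------------------------------------------------------------

@dataclass
class SpeciesDistanceMatrix:
    labels: list
    values: np.ndarray  # square, symmetric, zero diagonal, entries in [0, 1]
    trait_weights: dict = field(default_factory=dict)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise TraitSpaceError("distance matrix must be square")
        self.values = v


def _single_trait_distance(col: pd.Series, kind: str) -> np.ndarray:
    """n x n distance contribution of one plain trait column; NaN where a
    member of the pair is missing."""
    x = col.to_numpy()
    n = len(x)
    if kind in ("continuous", "binary"):
        xv = x.astype(float)
        d = np.abs(xv[:, None] - xv[None, :])
        if kind == "continuous":
            finite = xv[np.isfinite(xv)]
            rng = finite.max() - finite.min() if finite.size else 0.0
            d = d / rng if rng > 0 else np.zeros_like(d)
        miss = ~np.isfinite(xv)
    elif kind == "categorical":
        miss = pd.isna(x)
        d = (x[:, None] != x[None, :]).astype(float)
    else:  # pragma: no cover - guarded upstream
        raise TraitSpaceError(f"unknown trait type {kind!r}")
    d[miss, :] = np.nan
    d[:, miss] = np.nan
    np.fill_diagonal(d, 0.0)
    return d


def _fuzzy_group_distance(block: pd.DataFrame) -> np.ndarray:
    """Fuzzy-coded group (columns summing to 1 per species): mean over member
    columns of range-normalised absolute differences — the group acts as one
    variable."""
    mats = []
    for col in block.columns:
        xv = block[col].to_numpy(dtype=float)
        d = np.abs(xv[:, None] - xv[None, :])
        finite = xv[np.isfinite(xv)]
        rng = finite.max() - finite.min() if finite.size else 0.0
        d = d / rng if rng > 0 else np.zeros_like(d)
        miss = ~np.isfinite(xv)
        d[miss, :] = np.nan
        d[:, miss] = np.nan
        mats.append(d)
    out = np.nanmean(np.stack(mats), axis=0)
    np.fill_diagonal(out, 0.0)
    return out


def balanced_gower(
    traits: pd.DataFrame,
    trait_types: dict | None = None,
    fuzzy_groups: dict | None = None,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> SpeciesDistanceMatrix:
    """Gower distance over mixed trait types with balanced trait weights.

    Each plain column (continuous -> range-normalised |difference|;
    binary/categorical -> 0/1 mismatch) and each fuzzy-coded group (treated
    as a single variable) yields a [0,1] pairwise distance layer.  Weights
    ``w_t >= 0, sum w_t = 1`` are tuned by iterative proportional fitting so
    that every trait's mean pairwise contribution to the combined distance is
    equal.  Missing values use pairwise deletion with per-pair weight
    renormalisation.
    """
    n = traits.shape[0]
    if n < 2:
        raise TraitSpaceError("need at least 2 species")
    all_missing = traits.isna().all(axis=1)
    if all_missing.any():
        raise TraitSpaceError(
            f"species missing all traits: {list(traits.index[all_missing])}"
        )
    fuzzy_groups = fuzzy_groups or {}
    fuzzy_cols = {c for cols in fuzzy_groups.values() for c in cols}
    if trait_types is None:
        from .dataset import infer_trait_types

        trait_types = infer_trait_types(traits, fuzzy_groups)

    layers, names = [], []
    for col in traits.columns:
        if col in fuzzy_cols:
            continue
        layers.append(_single_trait_distance(traits[col], trait_types.get(col, "continuous")))
        names.append(col)
    for gname, cols in fuzzy_groups.items():
        layers.append(_fuzzy_group_distance(traits[list(cols)]))
        names.append(gname)
    if not layers:
        raise TraitSpaceError("no trait columns")

    D_layers = np.stack(layers)  # T x n x n
    iu = np.triu_indices(n, k=1)
    pair_d = D_layers[:, iu[0], iu[1]]  # T x P, NaN = pair unavailable for trait
    avail = np.isfinite(pair_d)

    # Constant traits cannot be balanced (their mean contribution is zero
    # whatever the weight); they keep the uniform base weight and contribute
    # zero distance, and the IPF balances the remaining (active) traits
    # within the rest of the weight budget.
    mean_d = np.array([np.nanmean(row) if np.isfinite(row).any() else 0.0 for row in pair_d])
    active = mean_d > 0
    T = len(names)
    w = np.full(T, 1.0 / T)
    if not active.any():
        log.warning("all traits constant: Gower distance is identically zero")
        return SpeciesDistanceMatrix(list(traits.index), np.zeros((n, n)), dict(zip(names, w)))
    budget = active.sum() / T  # weight mass shared by the active traits

    pd_filled = np.where(avail, pair_d, 0.0)
    for _ in range(max_iter):
        # per-pair renormalisation over available traits
        denom = (w[:, None] * avail).sum(axis=0)  # P
        contrib = np.where(denom > 0, (w[:, None] * pd_filled) / denom, 0.0)
        mean_contrib = np.array(
            [contrib[t, avail[t]].mean() if avail[t].any() else 0.0 for t in range(T)]
        )
        mc = mean_contrib[active]
        target = mc.mean()
        if target <= 0 or np.max(np.abs(mc - target)) < tol:
            break
        upd = np.ones(T)
        nz = active & (mean_contrib > 0)
        upd[nz] = target / mean_contrib[nz]
        w = w * upd
        w[active] *= budget / w[active].sum()

    denom = (w[:, None] * avail).sum(axis=0)
    combined_pairs = np.where(denom > 0, (w[:, None] * pd_filled).sum(axis=0) / denom, 0.0)
    D = np.zeros((n, n))
    D[iu] = combined_pairs
    D = D + D.T
    D = np.clip(D, 0.0, 1.0)
    return SpeciesDistanceMatrix(list(traits.index), D, dict(zip(names, w)))


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------

@dataclass
class TraitSpace:
    coordinates: np.ndarray  # species x k
    eigenvalues: np.ndarray
    labels: list
    negative_eigenvalue_flag: bool = False

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self._index = {lab: i for i, lab in enumerate(self.labels)}

    def coords_of(self, species) -> np.ndarray:
        idx = [self._index[s] for s in species]
        return self.coordinates[idx]

    @property
    def k(self) -> int:
        return self.coordinates.shape[1]


def pcoa_embed(D: SpeciesDistanceMatrix, k: int = 3, strict: bool = True) -> TraitSpace:
    """Classical scaling (principal coordinates) of a distance matrix.

    Double-centres the squared distances, eigendecomposes, and keeps the top
    ``k`` axes scaled by sqrt(eigenvalue).  No negative-eigenvalue correction
    is applied; if any retained eigenvalue is <= 0 the axis is zero-padded and
    the flag is set (strict mode raises instead).  Axis signs are fixed by
    making each axis's largest-magnitude loading positive.
    """
    d = D.values
    n = d.shape[0]
    if n < k + 1 and strict:
        raise TraitSpaceError(f"need at least {k + 1} species for a {k}-axis embedding")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (d ** 2) @ J
    B = (B + B.T) / 2
    vals, vecs = eigh(B)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    top = vals[:k]
    n_pos = int(np.sum(top > 1e-12))
    if n_pos < min(k, n) and strict:
        raise TraitSpaceError(
            f"only {n_pos} positive eigenvalues among the top {k}; reduce k"
        )
    coords = np.zeros((n, k))
    for j in range(min(k, n)):
        if vals[j] > 1e-12:
            axis = vecs[:, j] * np.sqrt(vals[j])
            if axis[np.argmax(np.abs(axis))] < 0:
                axis = -axis
            coords[:, j] = axis
    flag = bool(np.any(top <= 0))
    return TraitSpace(coords, np.asarray(vals[:k]), list(D.labels), flag)


def build_trait_space(
    traits: pd.DataFrame,
    trait_types: dict | None = None,
    fuzzy_groups: dict | None = None,
    k: int = 3,
) -> TraitSpace:
    """Convenience: balanced Gower then 3-axis PCoA (non-strict, pipeline path)."""
    D = balanced_gower(traits, trait_types, fuzzy_groups)
    return pcoa_embed(D, k=k, strict=False)


# ---------------------------------------------------------------------------
# Hypervolumes
# ---------------------------------------------------------------------------

@dataclass
class Hypervolume:
    """A community's occupied trait-space region: a Gaussian mixture with one
    kernel per member species, thresholded at the density enclosing mass
    quantile ``q``; volume estimated by rejection sampling."""

    kernel_centers: np.ndarray  # m x k
    kernel_weights: np.ndarray  # m, sums to 1
    bandwidth: np.ndarray       # k, positive
    density_threshold: float
    retained_points: np.ndarray  # points inside the region (from the box sample)
    volume: float
    seed: int
    n_samples: int
    bbox: tuple  # (lo, hi) arrays
    space_token: int = 0

    def density(self, pts: np.ndarray) -> np.ndarray:
        return _mixture_density(self.kernel_centers, self.kernel_weights, self.bandwidth, pts)

    def contains(self, pts: np.ndarray) -> np.ndarray:
        return self.density(pts) >= self.density_threshold


def _mixture_density(centers: np.ndarray, weights: np.ndarray, bw: np.ndarray, pts: np.ndarray) -> np.ndarray:
    # N x m x k squared standardised distances; vectorised Gaussian product kernel
    z = (pts[:, None, :] - centers[None, :, :]) / bw
    expo = -0.5 * np.einsum("nmk,nmk->nm", z, z)
    norm = weights / ((2 * np.pi) ** (centers.shape[1] / 2) * np.prod(bw))
    return np.exp(expo) @ norm


def silverman_bandwidth(X: np.ndarray, epsilon_bw: float = 1e-6) -> np.ndarray:
    """Per-axis Silverman rule for a d-dim Gaussian KDE, floored on
    zero-variance axes."""
    m, d = X.shape
    sd = X.std(axis=0, ddof=1) if m > 1 else np.zeros(d)
    factor = (4.0 / ((d + 2) * m)) ** (1.0 / (d + 4))
    bw = sd * factor
    return np.maximum(bw, epsilon_bw)


def build_hypervolume(
    space: TraitSpace,
    members,
    weights=None,
    seed: int = 0,
    n_samples: int = 2000,
    q: float = 0.95,
    min_species: int = 4,
    epsilon_bw: float = 1e-6,
) -> Hypervolume:
    """Build one community's hypervolume from its member species.

    Mixture weights are proportional to relative abundance (uniform when
    ``weights`` is None); bandwidths follow Silverman's rule per axis; the
    density threshold is set so the region encloses mass quantile ``q``
    (estimated from ``n_samples`` mixture draws); the volume is estimated by
    rejection sampling against the bounding box (member range +- 3 bandwidths).
    Deterministic given ``seed``.
    """
    X = space.coords_of(members) if not isinstance(members, np.ndarray) or members.ndim != 2 else members
    X = np.atleast_2d(np.asarray(X, dtype=float))
    m, k = X.shape
    if m < min_species:
        raise TraitSpaceError(f"community has {m} species; minimum is {min_species}")
    if weights is None:
        w = np.full(m, 1.0 / m)
    else:
        w = np.asarray(weights, dtype=float)
        if (w < 0).any() or w.sum() <= 0:
            raise TraitSpaceError("weights must be non-negative with positive sum")
        w = w / w.sum()

    bw = silverman_bandwidth(X, epsilon_bw)
    rng = np.random.default_rng(seed)

    comp = rng.choice(m, size=n_samples, p=w)
    draws = X[comp] + rng.standard_normal((n_samples, k)) * bw
    dens = _mixture_density(X, w, bw, draws)
    thr = float(np.quantile(dens, 1.0 - q))

    lo = X.min(axis=0) - 3.0 * bw
    hi = X.max(axis=0) + 3.0 * bw
    box_vol = float(np.prod(hi - lo))
    unif = rng.uniform(lo, hi, size=(n_samples, k))
    inside = _mixture_density(X, w, bw, unif) >= thr
    volume = box_vol * inside.mean()
    if volume <= 0:
        # 95% region of a floored-bandwidth kernel can slip between box samples
        volume = box_vol / n_samples

    return Hypervolume(
        kernel_centers=X,
        kernel_weights=w,
        bandwidth=bw,
        density_threshold=thr,
        retained_points=unif[inside],
        volume=float(volume),
        seed=int(seed),
        n_samples=int(n_samples),
        bbox=(lo, hi),
        space_token=id(space),
    )


def hypervolume_overlap(H1: Hypervolume, H2: Hypervolume, seed: int = 0, n_samples: int | None = None):
    """Monte-Carlo shared / unique volumes of two hypervolumes.

    Samples uniformly over the union bounding box and classifies points as
    inside both regions (a), only the first (b) or only the second (c).
    """
    if H1.space_token != H2.space_token:
        raise TraitSpaceError("hypervolumes were built in different trait spaces")
    n = n_samples or max(H1.n_samples, H2.n_samples)
    lo = np.minimum(H1.bbox[0], H2.bbox[0])
    hi = np.maximum(H1.bbox[1], H2.bbox[1])
    box_vol = float(np.prod(hi - lo))
    rng = np.random.default_rng(seed)
    pts = rng.uniform(lo, hi, size=(n, len(lo)))
    in1 = H1.contains(pts)
    in2 = H2.contains(pts)
    a = box_vol * np.mean(in1 & in2)
    b = box_vol * np.mean(in1 & ~in2)
    c = box_vol * np.mean(~in1 & in2)
    return float(a), float(b), float(c)


def union_volume(hypervolumes, seed: int = 0, n_samples: int | None = None) -> float:
    """Monte-Carlo volume of the union region of a list of hypervolumes."""
    hvs = list(hypervolumes)
    if not hvs:
        raise TraitSpaceError("empty hypervolume list")
    tok = hvs[0].space_token
    if any(h.space_token != tok for h in hvs):
        raise TraitSpaceError("hypervolumes were built in different trait spaces")
    n = n_samples or max(h.n_samples for h in hvs)
    lo = np.min([h.bbox[0] for h in hvs], axis=0)
    hi = np.max([h.bbox[1] for h in hvs], axis=0)
    box_vol = float(np.prod(hi - lo))
    rng = np.random.default_rng(seed)
    pts = rng.uniform(lo, hi, size=(n, len(lo)))
    inside = np.zeros(n, dtype=bool)
    for h in hvs:
        inside |= h.contains(pts)
    return float(box_vol * inside.mean())
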