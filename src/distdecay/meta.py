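"""Cross-dataset synthesis: dataset descriptors, paired t-tests on decay
strength, and boosted-regression-tree (BRT) models of the decay rates.

Each dataset is summarised by nine descriptors — absolute mean latitude,
spatial extent (largest pairwise site distance, km), realm, mean body size
(log10 g), dispersal mode, taxonomic gamma-diversity (species count),
functional gamma-diversity (union hypervolume volume, SD^3), number of sites
and number of environmental variables.  Decay rates across datasets are then
modelled with stagewise boosted shallow regression trees under Laplace
(absolute-error) loss, with the tree count chosen by 10-fold
cross-validation; relative influence, partial dependence, pairwise
interaction statistics and subsampling sensitivity follow gbm practice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import GradientBoostingRegressor
from sklearn.model_selection import KFold

from .dataset import CommunityDataset
from .distance import spatial_distance_matrix
from .traitspace import build_trait_space, build_hypervolume, union_volume

log = logging.getLogger(__name__)

PREDICTORS = [
    "latitude_abs_deg",
    "extent_km",
    "realm",
    "body_size_log10_g",
    "dispersal_mode",
    "gamma_tax",
    "gamma_fun",
    "n_sites",
    "n_env_vars",
]
CATEGORICAL = ("realm", "dispersal_mode")


@dataclass
class DatasetSummary:
    dataset: str
    latitude_abs_deg: float
    extent_km: float
    realm: str
    body_size_log10_g: float
    dispersal_mode: str
    gamma_tax: int
    gamma_fun: float
    n_sites: int
    n_env_vars: int

    def to_dict(self) -> dict:
        return {
            "dataset": self.dataset,
            "latitude_abs_deg": self.latitude_abs_deg,
            "extent_km": self.extent_km,
            "realm": self.realm,
            "body_size_log10_g": self.body_size_log10_g,
            "dispersal_mode": self.dispersal_mode,
            "gamma_tax": self.gamma_tax,
            "gamma_fun": self.gamma_fun,
            "n_sites": self.n_sites,
            "n_env_vars": self.n_env_vars,
        }


def summarize_dataset(
    ds: CommunityDataset,
    seed: int = 0,
    compute_gamma_fun: bool = True,
    n_samples: int = 1000,
    min_species: int = 4,
) -> DatasetSummary:
    """The nine cross-dataset descriptors of one dataset.

    Functional gamma-diversity is the Monte-Carlo volume of the union of the
    per-site hypervolumes (NaN when disabled or no site reaches the species
    minimum)."""
    lat_abs = float(abs(ds.coords.iloc[:, 0].astype(float).mean()))
    sdm = spatial_distance_matrix(ds.coords)
    extent = float(sdm.values.max()) if sdm.values.size else 0.0
    occ = ds.abundance.to_numpy(dtype=float) > 0
    gamma_tax = int((occ.any(axis=0)).sum())

    gamma_fun = float("nan")
    if compute_gamma_fun:
        space = build_trait_space(ds.traits, ds.trait_types, ds.fuzzy_groups)
        ss = np.random.SeedSequence(seed)
        seeds = ss.spawn(ds.n_sites + 1)
        hvs = []
        for i in range(ds.n_sites):
            members = np.flatnonzero(occ[i])
            if len(members) < min_species:
                continue
            hvs.append(
                build_hypervolume(
                    space, space.coordinates[members],
                    seed=seeds[i].generate_state(1)[0] % (2**31),
                    n_samples=n_samples, min_species=min_species,
                )
            )
        if hvs:
            gamma_fun = union_volume(
                hvs, seed=seeds[-1].generate_state(1)[0] % (2**31), n_samples=n_samples
            )

    return DatasetSummary(
        dataset=ds.name,
        latitude_abs_deg=lat_abs,
        extent_km=extent,
        realm=ds.meta.realm,
        body_size_log10_g=float(ds.meta.body_size_log10_g),
        dispersal_mode=ds.meta.dispersal_mode,
        gamma_tax=gamma_tax,
        gamma_fun=gamma_fun,
        n_sites=ds.n_sites,
        n_env_vars=ds.n_env,
    )


def build_meta_table(summaries, metrics_list, ses_list=None) -> pd.DataFrame:
    """One row per dataset: descriptors + the 4 Mantel r and 4 slopes (+ SES)."""
    rows = []
    ses_list = ses_list or [None] * len(summaries)
    for summ, met, ses in zip(summaries, metrics_list, ses_list):
        row = summ.to_dict()
        for facet in ("taxonomic", "functional"):
            for gradient in ("spatial", "environmental"):
                key = f"{facet[:3]}_{gradient[:3]}"
                row[f"mantel_r_{key}"] = met.mantel_r(facet, gradient)
                row[f"slope_{key}"] = met.slope(facet, gradient)
        if ses is not None:
            for s in ses:
                row[f"ses_{s.gradient[:3]}"] = s.ses
        rows.append(row)
    df = pd.DataFrame(rows)
    if df.dataset.duplicated().any():
        raise ValueError("duplicated dataset ids in meta table")
    return df.set_index("dataset")


def paired_t(x, y):
    """Student's paired t-test; returns (t, df, p) with a degenerate flag
    folded into p = NaN when the differences have zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need paired vectors of equal length >= 3")
    d = x - y
    if d.std(ddof=1) == 0:
        log.warning("paired t degenerate: zero variance of differences")
        return 0.0 if d.mean() == 0 else np.inf, x.size - 1, np.nan
    res = stats.ttest_rel(x, y)
    return float(res.statistic), int(x.size - 1), float(res.pvalue)


# ---------------------------------------------------------------------------
# Boosted regression trees (Laplace loss)
# ---------------------------------------------------------------------------

@dataclass
class BRTParams:
    learning_rate: float = 0.001
    tree_depth: int = 5
    bag_fraction: float = 0.5
    max_trees: int = 5000
    cv_folds: int = 10
    min_trees: int = 20


@dataclass
class BRTModel:
    """Fitted BRT results: the underlying estimator plus gbm-style summaries."""

    response: str
    loss: str
    n_trees_selected: int
    learning_rate: float
    tree_depth: int
    bag_fraction: float
    relative_influence: pd.Series
    deviance_explained_cv: float
    deviance_explained_train: float
    seed: int
    estimator: GradientBoostingRegressor = field(repr=False, default=None)
    feature_names: list = field(default_factory=list, repr=False)
    feature_of: dict = field(default_factory=dict, repr=False)   # one-hot col -> predictor
    X_design: pd.DataFrame = field(default=None, repr=False)
    table: pd.DataFrame = field(default=None, repr=False)
    cv_curve: np.ndarray = field(default=None, repr=False)

    def predict_table(self, table: pd.DataFrame) -> np.ndarray:
        X = _design(table, self.feature_names)
        return self.estimator.predict(X.to_numpy())

    def summary(self) -> str:
        ri = self.relative_influence.sort_values(ascending=False)
        lines = [
            f"Boosted regression trees ({self.loss} loss) on {self.response!r}",
            f"  trees (CV-selected): {self.n_trees_selected}   lr = {self.learning_rate}"
            f"   depth = {self.tree_depth}   bag = {self.bag_fraction}",
            f"  deviance explained (CV): {100 * self.deviance_explained_cv:.1f}%"
            f"   (train: {100 * self.deviance_explained_train:.1f}%)",
            "  relative influence (%):",
        ]
        lines += [f"    {name:<20s} {val:6.1f}" for name, val in ri.items()]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "loss": self.loss,
            "n_trees_selected": int(self.n_trees_selected),
            "learning_rate": self.learning_rate,
            "tree_depth": self.tree_depth,
            "bag_fraction": self.bag_fraction,
            "deviance_explained_cv": self.deviance_explained_cv,
            "deviance_explained_train": self.deviance_explained_train,
            "relative_influence": self.relative_influence.to_dict(),
            "seed": self.seed,
        }


def _design(table: pd.DataFrame, feature_names=None) -> pd.DataFrame:
    """One-hot design over the nine predictors (level-set splits are not
    available in the backend; one-hot influence is re-aggregated per
    predictor)."""
    cols = [c for c in PREDICTORS if c in table.columns]
    X = pd.get_dummies(table[cols], columns=[c for c in CATEGORICAL if c in cols])
    X = X.astype(float)
    if feature_names is not None:
        for c in feature_names:
            if c not in X.columns:
                X[c] = 0.0
        X = X[feature_names]
    return X


def _laplace_deviance(y, pred) -> float:
    return float(np.mean(np.abs(np.asarray(y) - np.asarray(pred))))


def fit_brt(
    table: pd.DataFrame,
    response: str,
    params: BRTParams | None = None,
    seed: int = 0,
    min_rows: int = 20,
) -> BRTModel:
    """Stagewise boosting of shallow trees under absolute-error (Laplace)
    loss, with the number of trees chosen at the minimum of the 10-fold
    cross-validated Laplace deviance (gbm.step style), then refitted on the
    full table.  Deterministic given the seed."""
    params = params or BRTParams()
    tbl = table.dropna(subset=[response] + [c for c in PREDICTORS if c in table.columns])
    if len(tbl) < min_rows:
        raise ValueError(f"need >= {min_rows} datasets for a BRT; got {len(tbl)}")
    y = tbl[response].to_numpy(dtype=float)
    if np.std(y) == 0:
        raise ValueError("constant response; nothing for a BRT to model")
    X = _design(tbl)
    feature_names = list(X.columns)
    Xv = X.to_numpy()

    def make_est(n_estimators):
        # tree_depth counts splits per tree (gbm's interaction.depth), hence
        # best-first trees with depth+1 leaves rather than depth levels
        return GradientBoostingRegressor(
            loss="absolute_error",
            learning_rate=params.learning_rate,
            n_estimators=n_estimators,
            max_depth=None,
            max_leaf_nodes=params.tree_depth + 1,
            subsample=params.bag_fraction,
            random_state=seed,
        )

    # 10-fold CV curve of Laplace deviance per boosting stage
    n_folds = min(params.cv_folds, len(tbl))
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    cv_dev = np.zeros(params.max_trees)
    for tr, te in kf.split(Xv):
        est = make_est(params.max_trees)
        est.fit(Xv[tr], y[tr])
        for stage, pred in enumerate(est.staged_predict(Xv[te])):
            cv_dev[stage] += np.abs(y[te] - pred).sum()
    cv_dev /= len(y)
    best = int(np.argmin(cv_dev[params.min_trees - 1:]) + params.min_trees)
    null_dev = _laplace_deviance(y, np.full_like(y, np.median(y)))
    dev_cv = 1.0 - cv_dev[best - 1] / null_dev

    est = make_est(best)
    est.fit(Xv, y)
    dev_train = 1.0 - _laplace_deviance(y, est.predict(Xv)) / null_dev

    # Per-split squared-improvement importances, with each tree's split
    # improvements scaled by that tree's realised reduction in the training
    # Laplace deviance.  (The raw impurity criterion is computed on the +-1
    # sign pseudo-residuals of the absolute-error loss, whose scale does not
    # shrink as the fit improves, so unweighted sums overstate late trees
    # that only chase noise.)  Aggregated back over one-hot levels.
    feature_of = {}
    for c in feature_names:
        parent = c
        for cat in CATEGORICAL:
            if c.startswith(cat + "_"):
                parent = cat
        feature_of[c] = parent
    tree_imp = np.zeros(len(feature_names))
    prev_dev = null_dev
    for k, pred in enumerate(est.staged_predict(Xv)):
        dev_k = _laplace_deviance(y, pred)
        delta = max(prev_dev - dev_k, 0.0)
        prev_dev = dev_k
        tree = est.estimators_[k, 0].tree_
        tree_imp += delta * tree.compute_feature_importances(normalize=True)
    if tree_imp.sum() <= 0:
        tree_imp = est.feature_importances_
    imp = pd.Series(tree_imp, index=feature_names)
    ri = imp.groupby(feature_of).sum()
    ri = ri.reindex([p for p in PREDICTORS if p in set(feature_of.values())]).fillna(0.0)
    total = ri.sum()
    ri = ri * (100.0 / total) if total > 0 else ri

    return BRTModel(
        response=response,
        loss="laplace",
        n_trees_selected=best,
        learning_rate=params.learning_rate,
        tree_depth=params.tree_depth,
        bag_fraction=params.bag_fraction,
        relative_influence=ri,
        deviance_explained_cv=float(dev_cv),
        deviance_explained_train=float(dev_train),
        seed=seed,
        estimator=est,
        feature_names=feature_names,
        feature_of=feature_of,
        X_design=X,
        table=tbl,
        cv_curve=cv_dev,
    )


def relative_influence(model: BRTModel) -> pd.Series:
    """Per-predictor relative influence (%), summing to 100."""
    return model.relative_influence.copy()


def _predictor_grid(model: BRTModel, predictor: str, n_points: int = 25):
    if predictor in CATEGORICAL:
        return sorted(model.table[predictor].unique())
    x = model.table[predictor].to_numpy(dtype=float)
    return np.linspace(x.min(), x.max(), n_points)


def partial_dependence(model: BRTModel, predictor: str, grid=None) -> pd.DataFrame:
    """Mean prediction over the table with ``predictor`` forced to each grid
    value, centred to mean zero (positive = steeper than the mean rate)."""
    if grid is None:
        grid = _predictor_grid(model, predictor)
    else:
        if predictor not in CATEGORICAL:
            g = np.asarray(grid, dtype=float)
            x = model.table[predictor].to_numpy(dtype=float)
            if g.min() < x.min() or g.max() > x.max():
                log.warning("partial dependence grid extends outside the observed range")
    effects = []
    for g in grid:
        tbl = model.table.copy()
        tbl[predictor] = g
        effects.append(float(np.mean(model.predict_table(tbl))))
    effects = np.asarray(effects)
    effects = effects - effects.mean()
    return pd.DataFrame({"predictor": predictor, "grid": list(grid), "centred_effect": effects})


def interaction_strength(model: BRTModel, pair, n_points: int = 20) -> float:
    """gbm-style pairwise interaction size: predictions on a 2-D grid of the
    pair (other predictors held at median/mode) are fitted with an additive
    model in the two grid margins; the statistic is the residual variance of
    the non-additive remainder x 1000."""
    p1, p2 = pair
    g1 = _predictor_grid(model, p1, n_points)
    g2 = _predictor_grid(model, p2, n_points)

    base = {}
    for c in model.table.columns:
        if c in CATEGORICAL:
            base[c] = model.table[c].mode().iloc[0]
        elif c in PREDICTORS:
            base[c] = float(model.table[c].median())
    rows = []
    for a in g1:
        for b in g2:
            r = dict(base)
            r[p1], r[p2] = a, b
            rows.append(r)
    grid_tbl = pd.DataFrame(rows)
    pred = model.predict_table(grid_tbl)

    # additive saturated-margin model: dummies for each margin level
    f1 = pd.get_dummies(pd.Categorical([r[p1] for r in rows]), drop_first=True).to_numpy(float)
    f2 = pd.get_dummies(pd.Categorical([r[p2] for r in rows]), drop_first=True).to_numpy(float)
    Xa = np.column_stack([np.ones(len(rows)), f1, f2])
    beta, *_ = np.linalg.lstsq(Xa, pred, rcond=None)
    resid = pred - Xa @ beta
    return float(np.var(resid) * 1000.0)


def sensitivity_subsample(
    table: pd.DataFrame,
    response: str,
    fractions=(0.9, 0.7, 0.5),
    n_reps: int = 10,
    seed: int = 0,
    params: BRTParams | None = None,
    min_rows: int = 20,
) -> pd.DataFrame:
    """Refit the BRT on row subsamples (without replacement) of the meta
    table; reports per-rep relative influences and the top-ranked predictor
    so rank stability across sample sizes can be checked."""
    rng = np.random.default_rng(seed)
    rows = []
    for frac in fractions:
        n_sub = int(round(frac * len(table)))
        for rep in range(n_reps):
            idx = rng.choice(len(table), size=n_sub, replace=False)
            sub = table.iloc[idx]
            model = fit_brt(sub, response, params=params,
                            seed=int(rng.integers(0, 2**31 - 1)),
                            min_rows=min(min_rows, n_sub))
            ri = model.relative_influence
            rec = {"fraction": frac, "rep": rep, "n_rows": n_sub,
                   "top_predictor": ri.idxmax(),
                   "deviance_explained_cv": model.deviance_explained_cv}
            rec.update({f"ri_{k}": v for k, v in ri.items()})
            rows.append(rec)
    return pd.DataFrame(rows)
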