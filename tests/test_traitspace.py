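import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.stats import chi2

from distdecay.traitspace import (
    TraitSpace,
    TraitSpaceError,
    balanced_gower,
    build_hypervolume,
    hypervolume_overlap,
    pcoa_embed,
    union_volume,
)


def _space_from_points(pts, labels=None):
    pts = np.asarray(pts, dtype=float)
    labels = labels or [f"s{i}" for i in range(len(pts))]
    return TraitSpace(pts, np.ones(pts.shape[1]), labels)


class TestBalancedGower:
    def test_identical_species_have_zero_distance(self):
        traits = pd.DataFrame(
            {"a": [1.0, 1.0, 3.0], "b": [0.0, 0.0, 1.0]}, index=["x", "y", "z"]
        )
        D = balanced_gower(traits)
        assert D.values[0, 1] == 0.0
        assert np.all(np.diag(D.values) == 0)

    def test_single_binary_mismatch_among_four_traits(self):
        # only one of four equally-weighted traits differs -> distance 1/4
        traits = pd.DataFrame(
            {
                "c1": [1.0, 1.0],
                "c2": [2.0, 2.0],
                "b1": [0.0, 1.0],
                "b2": [1.0, 1.0],
            },
            index=["x", "y"],
        )
        D = balanced_gower(traits)
        assert D.values[0, 1] == pytest.approx(0.25)

    def test_mean_contributions_equalized(self):
        rng = np.random.default_rng(3)
        traits = pd.DataFrame(
            {
                "cont": rng.uniform(0, 10, 5),
                "bin": rng.integers(0, 2, 5).astype(float),
                "cat": pd.Categorical(rng.choice(list("pqr"), 5)),
            },
            index=[f"s{i}" for i in range(5)],
        )
        D = balanced_gower(traits)
        w = D.trait_weights
        # direct recomputation of per-trait mean contributions
        cont = np.abs(np.subtract.outer(traits["cont"].to_numpy(), traits["cont"].to_numpy()))
        cont /= cont.max()
        bi = np.abs(np.subtract.outer(traits["bin"].to_numpy(), traits["bin"].to_numpy()))
        cat = (traits["cat"].to_numpy()[:, None] != traits["cat"].to_numpy()[None, :]).astype(float)
        iu = np.triu_indices(5, 1)
        contribs = [w["cont"] * cont[iu].mean(), w["bin"] * bi[iu].mean(), w["cat"] * cat[iu].mean()]
        assert max(contribs) - min(contribs) < 1e-9
        assert sum(w.values()) == pytest.approx(1.0)

    def test_symmetry_range_and_fuzzy_group_counts_once(self):
        rng = np.random.default_rng(8)
        memb = rng.dirichlet(np.ones(3), size=6)
        traits = pd.DataFrame(
            np.column_stack([rng.uniform(size=6), memb]),
            columns=["cont", "f1", "f2", "f3"],
            index=[f"s{i}" for i in range(6)],
        )
        D = balanced_gower(traits, fuzzy_groups={"guild": ["f1", "f2", "f3"]})
        v = D.values
        assert np.allclose(v, v.T)
        assert v.min() >= 0 and v.max() <= 1
        assert set(D.trait_weights) == {"cont", "guild"}

    def test_errors(self):
        one = pd.DataFrame({"a": [1.0]}, index=["x"])
        with pytest.raises(TraitSpaceError):
            balanced_gower(one)
        missing = pd.DataFrame({"a": [1.0, np.nan], "b": [2.0, np.nan]}, index=["x", "y"])
        with pytest.raises(TraitSpaceError, match="y"):
            balanced_gower(missing)


class TestPCoA:
    def test_euclidean_input_is_reproduced_exactly(self):
        rng = np.random.default_rng(0)
        pts = rng.standard_normal((5, 3))
        D = balanced_gower(pd.DataFrame({"a": [0.0] * 5}, index=list("abcde")))
        D.values = squareform(pdist(pts))
        space = pcoa_embed(D, k=3)
        got = pdist(space.coordinates)
        assert np.allclose(got, pdist(pts), atol=1e-9)
        assert not space.negative_eigenvalue_flag
        # axes ordered by decreasing eigenvalue
        assert np.all(np.diff(space.eigenvalues) <= 1e-12)

    def test_embedding_correlates_with_gower_distance(self):
        rng = np.random.default_rng(5)
        traits = pd.DataFrame(
            {
                "a": rng.uniform(size=10),
                "b": rng.integers(0, 2, 10).astype(float),
                "c": rng.uniform(size=10),
            },
            index=[f"s{i}" for i in range(10)],
        )
        D = balanced_gower(traits)
        space = pcoa_embed(D, k=3)
        emb = pdist(space.coordinates)
        orig = squareform(D.values)
        r = np.corrcoef(emb, orig)[0, 1]
        assert r >= 0.9

    def test_too_few_species_raises(self):
        traits = pd.DataFrame({"a": [0.0, 1.0]}, index=["x", "y"])
        D = balanced_gower(traits)
        with pytest.raises(TraitSpaceError):
            pcoa_embed(D, k=3, strict=True)

    def test_nonstrict_pads_and_flags(self):
        traits = pd.DataFrame({"a": [1.0, 1.0, 1.0, 1.0]}, index=list("wxyz"))
        D = balanced_gower(traits)  # all-zero distances
        space = pcoa_embed(D, k=3, strict=False)
        assert space.coordinates.shape == (4, 3)
        assert np.allclose(space.coordinates, 0.0)
        assert space.negative_eigenvalue_flag

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(11)
        traits = pd.DataFrame(
            rng.uniform(size=(8, 3)), columns=list("abc"), index=[f"s{i}" for i in range(8)]
        )
        D = balanced_gower(traits)
        s1 = pcoa_embed(D, k=3)
        s2 = pcoa_embed(D, k=3)
        assert np.array_equal(s1.coordinates, s2.coordinates)
        for j in range(3):
            col = s1.coordinates[:, j]
            if np.any(col != 0):
                assert col[np.argmax(np.abs(col))] > 0


class TestHypervolume:
    def test_single_kernel_matches_analytic_gaussian_ellipsoid(self):
        space = _space_from_points([[0.0, 0.0, 0.0]])
        h = build_hypervolume(space, ["s0"], seed=1, n_samples=20000, min_species=1)
        r2 = chi2.ppf(0.95, 3)
        analytic = 4.0 / 3.0 * np.pi * r2**1.5 * np.prod(h.bandwidth)
        assert h.volume == pytest.approx(analytic, rel=0.15)

    def test_determinism_given_seed(self):
        rng = np.random.default_rng(2)
        space = _space_from_points(rng.standard_normal((6, 3)))
        h1 = build_hypervolume(space, space.labels, seed=9, n_samples=2000)
        h2 = build_hypervolume(space, space.labels, seed=9, n_samples=2000)
        assert h1.volume == h2.volume
        assert np.array_equal(h1.retained_points, h2.retained_points)

    def test_duplicated_members_leave_volume_unchanged(self):
        rng = np.random.default_rng(4)
        pts = rng.standard_normal((5, 3))
        s1 = _space_from_points(pts)
        h1 = build_hypervolume(s1, s1.labels, seed=3, n_samples=20000)
        # duplicating every kernel leaves the mixture identical up to bandwidth
        s2 = _space_from_points(np.vstack([pts, pts]))
        h2 = build_hypervolume(
            s2, s2.labels, seed=3, n_samples=20000, min_species=1
        )
        # bandwidth shrinks with m; compare against a same-bandwidth rebuild
        h2.bandwidth[:] = h1.bandwidth
        # mixture density with duplicated equal-weight kernels is identical
        q = rng.standard_normal((100, 3))
        assert np.allclose(h1.density(q), h2.density(q))

    def test_min_species_enforced(self):
        space = _space_from_points(np.zeros((2, 3)))
        with pytest.raises(TraitSpaceError, match="minimum"):
            build_hypervolume(space, space.labels, seed=0)

    def test_retained_points_are_inside_region(self):
        rng = np.random.default_rng(6)
        space = _space_from_points(rng.standard_normal((6, 3)))
        h = build_hypervolume(space, space.labels, seed=5, n_samples=3000)
        assert h.volume > 0
        assert np.all(h.density(h.retained_points) >= h.density_threshold)


class TestOverlap:
    def _pair(self, offset, seed=0, m=5, n=20000):
        rng = np.random.default_rng(seed)
        pts = rng.standard_normal((m, 3))
        space = _space_from_points(np.vstack([pts, pts + offset]))
        h1 = build_hypervolume(space, space.labels[:m], seed=1, n_samples=n)
        h2 = build_hypervolume(space, space.labels[m:], seed=2, n_samples=n)
        return h1, h2

    def test_self_overlap(self):
        h1, _ = self._pair(np.zeros(3))
        a, b, c = hypervolume_overlap(h1, h1, seed=3)
        assert b == 0.0 and c == 0.0
        assert a == pytest.approx(h1.volume, rel=0.05)

    def test_disjoint_clouds_share_nothing(self):
        h1, h2 = self._pair(np.array([50.0, 0.0, 0.0]))
        a, b, c = hypervolume_overlap(h1, h2, seed=4)
        assert a <= 0.02 * (h1.volume + h2.volume)
        assert b == pytest.approx(h1.volume, rel=0.1)
        assert c == pytest.approx(h2.volume, rel=0.1)

    def test_volume_consistency_a_plus_b(self):
        h1, h2 = self._pair(np.array([0.5, 0.5, 0.0]), seed=7)
        a, b, c = hypervolume_overlap(h1, h2, seed=5)
        assert abs((a + b) - h1.volume) / h1.volume <= 0.1
        assert abs((a + c) - h2.volume) / h2.volume <= 0.1

    def test_single_kernel_offset_matches_1d_analytic_interval(self):
        # two single-kernel regions offset along one axis: the shared volume
        # is the cross-section area times the 1-D interval intersection
        space = _space_from_points([[0.0, 0.0, 0.0], [1e-6, 0.0, 0.0]])
        h1 = build_hypervolume(space, ["s0"], seed=1, n_samples=40000, min_species=1)
        h2 = build_hypervolume(space, ["s1"], seed=2, n_samples=40000, min_species=1)
        a, b, c = hypervolume_overlap(h1, h2, seed=6, n_samples=200000)
        # offset = 1 bandwidth (both bandwidths floored at 1e-6); each region
        # is a ball of radius r bandwidths, so the shared volume is the
        # sphere-sphere lens, integrated directly as the analytic oracle
        import scipy.integrate as si

        r = np.sqrt(chi2.ppf(0.95, 3))  # ball radius in bandwidth units
        d = 1.0                         # centre offset in bandwidth units

        def cross_section(x):
            return np.pi * min(max(r**2 - x**2, 0.0), max(r**2 - (x - d) ** 2, 0.0))

        lens, _ = si.quad(cross_section, d - r, r)
        expected = lens * np.prod(h1.bandwidth)
        assert a == pytest.approx(expected, rel=0.10)

    def test_incompatible_spaces_fatal(self):
        s1 = _space_from_points(np.zeros((4, 3)))
        s2 = _space_from_points(np.zeros((4, 3)))
        h1 = build_hypervolume(s1, s1.labels, seed=1)
        h2 = build_hypervolume(s2, s2.labels, seed=1)
        with pytest.raises(TraitSpaceError, match="spaces"):
            hypervolume_overlap(h1, h2)


class TestUnionVolume:
    def test_single_and_idempotent(self):
        rng = np.random.default_rng(9)
        space = _space_from_points(rng.standard_normal((5, 3)))
        h = build_hypervolume(space, space.labels, seed=2, n_samples=20000)
        assert union_volume([h], seed=1, n_samples=50000) == pytest.approx(h.volume, rel=0.05)
        assert union_volume([h, h], seed=1, n_samples=50000) == pytest.approx(h.volume, rel=0.05)

    def test_disjoint_additivity(self):
        rng = np.random.default_rng(10)
        pts = rng.standard_normal((5, 3))
        offset = np.array([12.0, 0.0, 0.0])  # far beyond any bandwidth: disjoint
        space = _space_from_points(np.vstack([pts, pts + offset]))
        h1 = build_hypervolume(space, space.labels[:5], seed=3, n_samples=20000)
        h2 = build_hypervolume(space, space.labels[5:], seed=4, n_samples=20000)
        u = union_volume([h1, h2], seed=5, n_samples=500000)
        assert u == pytest.approx(h1.volume + h2.volume, rel=0.1)

    def test_bounds(self):
        rng = np.random.default_rng(12)
        pts = rng.standard_normal((6, 3))
        space = _space_from_points(np.vstack([pts, pts + 0.8]))
        h1 = build_hypervolume(space, space.labels[:6], seed=6, n_samples=20000)
        h2 = build_hypervolume(space, space.labels[6:], seed=7, n_samples=20000)
        u = union_volume([h1, h2], seed=8, n_samples=100000)
        assert u >= 0.9 * max(h1.volume, h2.volume)
        assert u <= 1.1 * (h1.volume + h2.volume)


class TestConvergence:
    def test_doubling_samples_shrinks_volume_dispersion(self):
        rng = np.random.default_rng(13)
        space = _space_from_points(rng.standard_normal((6, 3)))
        vols = {n: [] for n in (500, 1000)}
        for n in vols:
            for seed in range(24):
                vols[n].append(
                    build_hypervolume(space, space.labels, seed=seed, n_samples=n).volume
                )
        assert np.std(vols[1000]) < np.std(vols[500])
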