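import itertools

import numpy as np
import pandas as pd
import pytest

from diallelkit.distances import (
    DistanceMatrix,
    cross_statistic_to_matrix,
    euclidean_matrix,
    mahalanobis_matrix,
    mantel,
)
from diallelkit.simulate import SimulationSpec, default_design, simulate_diallel


def _dist(arr, labels=None, kind="cross_statistic"):
    labels = labels or [f"P{i + 1}" for i in range(len(arr))]
    return DistanceMatrix(values=pd.DataFrame(arr, index=labels, columns=labels),
                          kind=kind)


def _random_distance(n, seed):
    rng = np.random.default_rng(seed)
    pts = rng.normal(size=(n, 3))
    d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
    return _dist(d, kind="euclidean")


class TestEuclidean:
    def test_identical_profiles_zero(self):
        prof = pd.DataFrame([[1.0, 2.0], [1.0, 2.0], [3.0, 0.0]],
                            index=list("ABC"), columns=["t1", "t2"])
        d = euclidean_matrix(prof)
        assert d.values.loc["A", "B"] == pytest.approx(0.0)

    def test_unit_difference_in_four_standardized_traits(self):
        """Profiles already on the standardized scale differing by 1 in each
        of 4 traits are sqrt(4) = 2 apart."""
        prof = pd.DataFrame([[0.0] * 4, [1.0] * 4, [0.5] * 4],
                            index=list("ABC"))
        d = euclidean_matrix(prof, standardize=False)
        assert d.values.loc["A", "B"] == pytest.approx(2.0)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(3)
        prof = pd.DataFrame(rng.normal(size=(6, 5)),
                            index=[f"P{i}" for i in range(6)])
        d = euclidean_matrix(prof)
        z = (prof - prof.mean()) / prof.std(ddof=1)
        for a, b in itertools.combinations(prof.index, 2):
            expected = np.sqrt(((z.loc[a] - z.loc[b]) ** 2).sum())
            assert d.values.loc[a, b] == pytest.approx(expected, abs=1e-10)

    def test_incomplete_parent_excluded(self):
        prof = pd.DataFrame([[1.0, 2.0], [np.nan, 1.0], [0.0, 0.0], [2.0, 1.0]],
                            index=list("ABCD"))
        d = euclidean_matrix(prof)
        assert "B" not in d.labels
        assert d.values.attrs["excluded_parents"] == ["B"]


def _multitrait_records(seed=0, n_traits=3):
    d = default_design(method="method2", n_envs=1)
    frames = []
    for t in range(n_traits):
        r, _ = simulate_diallel(SimulationSpec(design=d, trait=f"t{t}",
                                               seed=seed * 100 + t))
        frames.append(r)
    return pd.concat(frames, ignore_index=True), d, [f"t{t}" for t in range(n_traits)]


class TestMahalanobis:
    def test_identical_group_means_zero(self):
        d = default_design(method="method2", n_envs=1)
        frames = []
        for t in ("a", "b"):
            r, _ = simulate_diallel(SimulationSpec(
                design=d, trait=t, sigma2_g=0, sigma2_s=0, sigma2_gE=0,
                sigma2_sE=0, sigma2_block=0, sigma2_e=0.5,
                seed=1 if t == "a" else 2))
            frames.append(r)
        records = pd.concat(frames, ignore_index=True)
        dm = mahalanobis_matrix(records, ["a", "b"], "E1", d)
        # no genetic signal: distances stay modest and the diagonal is exact 0
        assert np.allclose(np.diag(dm.values.to_numpy()), 0.0)

    def test_canonical_space_equivalence(self):
        """D2 from the W-inverse quadratic form equals the squared Euclidean
        distance between group means in the whitened (canonical) space."""
        records, d, traits = _multitrait_records(seed=5)
        dm = mahalanobis_matrix(records, traits, "E1", d)
        sub = records[(records["parent_a"] == records["parent_b"])
                      & (records["env"] == "E1")]
        wide = sub.pivot_table(index=["parent_a", "block"], columns="trait",
                               values="value").reindex(columns=traits)
        W = np.zeros((len(traits), len(traits)))
        dfw = 0
        means = {}
        for g in d.parents:
            block = wide.loc[g].to_numpy()
            means[g] = block.mean(axis=0)
            dev = block - block.mean(axis=0)
            W += dev.T @ dev
            dfw += len(block) - 1
        W /= dfw
        L = np.linalg.cholesky(np.linalg.inv(W))
        for a, b in itertools.combinations(d.parents, 2):
            z = (means[a] - means[b]) @ L
            assert dm.values.loc[a, b] == pytest.approx(z @ z, abs=1e-8)

    def test_linear_transform_invariance(self):
        records, d, traits = _multitrait_records(seed=6)
        dm = mahalanobis_matrix(records, traits, "E1", d)
        rng = np.random.default_rng(0)
        A = rng.normal(size=(3, 3)) + 3 * np.eye(3)
        transformed = records.copy()
        wide = transformed.pivot_table(
            index=["env", "block", "parent_a", "parent_b"], columns="trait",
            values="value").reindex(columns=traits)
        new = pd.DataFrame(wide.to_numpy() @ A.T, index=wide.index, columns=traits)
        new.columns.name = "trait"
        long = new.stack().rename("value").reset_index()
        dm2 = mahalanobis_matrix(long, traits, "E1", d)
        np.testing.assert_allclose(dm.values.to_numpy(), dm2.values.to_numpy(),
                                   atol=1e-6)

    def test_singular_covariance_rejected(self):
        records, d, traits = _multitrait_records(seed=7)
        dup = records[records["trait"] == "t0"].assign(trait="t_copy")
        rec = pd.concat([records, dup], ignore_index=True)
        with pytest.raises((ValueError, np.linalg.LinAlgError)):
            mahalanobis_matrix(rec, traits + ["t_copy"], "E1", d)


class TestCrossStatisticMatrix:
    def test_full_half_diallel(self):
        parents = [f"P{i}" for i in range(1, 9)]
        values = {(a, b): float(i) for i, (a, b) in
                  enumerate(itertools.combinations(parents, 2))}
        m = cross_statistic_to_matrix(values, parents)
        assert m.values.shape == (8, 8)
        arr = m.values.to_numpy()
        np.testing.assert_allclose(arr, arr.T)
        assert np.allclose(np.diag(arr), 0.0)

    def test_round_trip_identity(self):
        parents = list("ABCD")
        values = {pair: float(i % 7) for i, pair in
                  enumerate(itertools.combinations(parents, 2))}
        m = cross_statistic_to_matrix(values, parents)
        back = {(a, b): m.values.loc[a, b] for a, b in
                itertools.combinations(parents, 2)}
        assert back == values

    def test_missing_cross_rejected(self):
        with pytest.raises(ValueError, match="missing cross"):
            cross_statistic_to_matrix({("A", "B"): 1.0}, list("ABC"))


class TestMantel:
    def test_self_correlation_is_one(self):
        A = _random_distance(6, 1)
        res = mantel(A, A, n_perm=199, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.p_value < 0.05

    def test_exact_enumeration_matches_brute_force(self):
        """At p=4 all 24 relabelings are enumerated; compare with an
        independent brute-force oracle."""
        A = _random_distance(4, 2)
        B = _random_distance(4, 3)
        res = mantel(A, B, exact=True)
        a = A.condensed()
        bfull = B.values.to_numpy()
        iu = np.triu_indices(4, 1)
        r_obs = np.corrcoef(a, bfull[iu])[0, 1]
        count = sum(
            np.corrcoef(a, bfull[np.ix_(perm, perm)][iu])[0, 1] >= r_obs - 1e-12
            for perm in map(np.array, itertools.permutations(range(4)))
        )
        assert res.n_perm == 24
        assert res.p_value == pytest.approx(count / 24)

    def test_sampled_p_close_to_exact(self):
        A = _random_distance(5, 4)
        B = _random_distance(5, 5)
        exact = mantel(A, B, exact=True)
        sampled = mantel(A, B, n_perm=4999, seed=7)
        assert sampled.r == pytest.approx(exact.r)
        assert sampled.p_value == pytest.approx(exact.p_value, abs=0.03)

    def test_symmetry_in_r(self):
        A = _random_distance(6, 8)
        B = _random_distance(6, 9)
        assert mantel(A, B, n_perm=99, seed=0).r == \
            pytest.approx(mantel(B, A, n_perm=99, seed=0).r)

    def test_label_mismatch_rejected(self):
        A = _random_distance(4, 1)
        B = _dist(A.values.to_numpy(), labels=list("WXYZ"), kind="euclidean")
        with pytest.raises(ValueError, match="labels"):
            mantel(A, B, n_perm=99)

    def test_power_when_matrices_are_related(self):
        """A genetic-distance matrix built to covary with a phenotypic one is
        detected with high power at moderate effect size."""
        rng = np.random.default_rng(11)
        hits = 0
        for _ in range(25):
            base = rng.normal(size=(8, 3))
            d1 = np.linalg.norm(base[:, None] - base[None, :], axis=2)
            noise = rng.normal(size=(8, 3)) * 0.4
            pts2 = base + noise
            d2 = np.linalg.norm(pts2[:, None] - pts2[None, :], axis=2)
            res = mantel(_dist(d1, kind="euclidean"), _dist(d2, kind="euclidean"),
                         n_perm=299, seed=int(rng.integers(2**31 - 1)))
            hits += res.p_value < 0.05
        assert hits / 25 > 0.8


class TestDistanceMatrixValidation:
    def test_asymmetric_rejected(self):
        arr = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            _dist(arr)

    def test_negative_true_distance_rejected(self):
        arr = np.array([[0.0, -1.0], [-1.0, 0.0]])
        with pytest.raises(ValueError, match="nonnegative"):
            _dist(arr, kind="euclidean")

    def test_signed_cross_statistic_allowed(self):
        arr = np.array([[0.0, -1.0], [-1.0, 0.0]])
        assert _dist(arr, kind="cross_statistic").values.shape == (2, 2)
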