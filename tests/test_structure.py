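import itertools

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

import cgsa
from cgsa.extract import SummaryMatrix
from cgsa.structure import (
    PAM,
    angular_order,
    centroid_correlation,
    choose_k,
    circular_rank_agreement,
    cluster_centroids,
    map_gene_sets,
    pam_cluster,
    principal_plane,
    project_external,
)


def _summary(values, set_ids=None, sample_ids=None):
    values = np.asarray(values, dtype=float)
    n_sets, n_samp = values.shape
    return SummaryMatrix(
        set_ids=set_ids or [f"CGS{k + 1:02d}" for k in range(n_sets)],
        sample_ids=sample_ids or [f"S{j + 1:03d}" for j in range(n_samp)],
        values=values,
        weights=[[] for _ in range(n_sets)],
        signs=np.ones(n_sets),
        means=np.zeros(n_sets),
        sds=np.ones(n_sets),
    )


class TestPrincipalPlane:
    def test_rank_one_data_second_coordinate_zero(self):
        t = np.linspace(-2, 2, 9)
        S = _summary(np.vstack([t, 2 * t, -0.5 * t]))
        plane = principal_plane(S)
        np.testing.assert_allclose(plane.coords[:, 1], 0, atol=1e-10)

    def test_variance_ordering(self, rng):
        S = _summary(rng.normal(size=(6, 30)))
        plane = principal_plane(S)
        assert plane.coords[:, 0].var() >= plane.coords[:, 1].var()

    def test_matches_eigendecomposition(self, rng):
        S = _summary(rng.normal(size=(5, 25)))
        plane = principal_plane(S)
        D = S.values.T
        Dc = D - D.mean(axis=0)
        cov = np.cov(Dc, rowvar=False, ddof=1)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        for j, comp in enumerate(order[:2]):
            v = evecs[:, comp]
            if v[np.argmax(np.abs(v))] < 0:
                v = -v
            np.testing.assert_allclose(np.abs(Dc @ v), np.abs(plane.coords[:, j]), atol=1e-10)

    def test_axis_beyond_rank_errors(self, rng):
        S = _summary(rng.normal(size=(3, 20)))
        with pytest.raises(ValueError, match="axis"):
            principal_plane(S, axes=(1, 7))


class TestAngularOrder:
    def _plane(self, pts, ref=(1.0, 0.0)):
        pts = np.asarray(pts, dtype=float)
        from cgsa.structure import PlaneProjection

        plane = PlaneProjection(
            sample_ids=[f"S{j}" for j in range(len(pts))],
            coords=pts,
            loadings=np.eye(2),
            axes=(1, 2),
            mean_=np.zeros(2),
        )
        return angular_order(plane, reference=ref)

    def test_axis_aligned_geometry(self):
        o = self._plane([(1, 0), (0, 1), (-1, 0), (0, -1)])
        np.testing.assert_allclose(o.angles, [0, np.pi / 2, np.pi, 3 * np.pi / 2], atol=1e-12)
        assert o.order == ["S0", "S1", "S2", "S3"]

    def test_rotation_invariance(self, rng):
        pts = rng.normal(size=(12, 2))
        base = self._plane(pts, ref=(1.0, 0.5))
        theta = 1.1
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        ref_rot = R @ np.array([1.0, 0.5])
        rot = self._plane(pts @ R.T, ref=tuple(ref_rot))
        assert base.order == rot.order

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            self._plane([(1, 0), (0, 1), (1, 1)], ref=(0.0, 0.0))

    def test_zero_vectors_placed_last_by_id(self):
        o = self._plane([(0, 0), (1, 0), (0, 0), (0, 1)])
        assert o.order == ["S1", "S3", "S0", "S2"]

    def test_circular_agreement_of_rotated_copy(self):
        ids = [f"S{j}" for j in range(20)]
        rotated = ids[7:] + ids[:7]
        assert circular_rank_agreement(ids, rotated) == pytest.approx(1.0)
        assert circular_rank_agreement(ids, rotated[::-1]) == pytest.approx(-1.0)


class TestProjectExternal:
    @pytest.fixture(scope="class")
    def separated(self):
        design = cgsa.default_design(n_samples=750, cluster_shift=3.0)
        X, _, truth = cgsa.simulate_cohort(design, seed=5)
        ref_ids = X.sample_ids[:150]
        Xref = X.subset_samples(ref_ids)
        coll = cgsa.extract_cgs_collection(Xref, n_sets=10, r_min=0.6)
        S = cgsa.summarize_cgs(Xref, coll)
        plane = principal_plane(S)
        return X, truth, ref_ids, Xref, coll, S, plane

    def test_reference_projection_idempotent(self, separated):
        X, truth, ref_ids, Xref, coll, S, plane = separated
        pe = project_external(S, Xref, coll, plane=plane)
        np.testing.assert_allclose(pe.coords, plane.coords, atol=1e-10)

    def test_mean_sample_lands_at_origin(self, separated):
        from cgsa.exprio import ExpressionMatrix

        X, truth, ref_ids, Xref, coll, S, plane = separated
        # a sample at the per-gene reference mean summarises to the per-set
        # mean and is centred away by the plane mean
        mean_sample = ExpressionMatrix(
            Xref.gene_ids, ["MEAN"], Xref.values.mean(axis=1, keepdims=True)
        )
        pe = project_external(S, mean_sample, coll, plane=plane)
        np.testing.assert_allclose(pe.coords, 0, atol=1e-8)

    def test_externals_land_nearest_own_centroid(self, separated):
        X, truth, ref_ids, Xref, coll, S, plane = separated
        lab_ref = np.array([truth.sample_cluster[s] for s in ref_ids])
        cents = {c: plane.coords[lab_ref == c].mean(axis=0) for c in range(3)}
        ext_ids = [s for s in X.sample_ids[150:] if truth.sample_cluster[s] == 2][:200]
        pe = project_external(S, X.subset_samples(ext_ids), coll, plane=plane)
        hits = sum(
            min(cents, key=lambda c: np.linalg.norm(pe.coords[i] - cents[c])) == 2
            for i in range(len(ext_ids))
        )
        assert hits / len(ext_ids) >= 0.95


class TestMapGeneSets:
    def test_full_target_retains_everything(self, fitted_cohort):
        X, _, _, coll, _ = fitted_cohort
        mapped = map_gene_sets(coll, X.gene_ids)
        assert all(s.retained_fraction == 1.0 and s.mapped for s in mapped.sets)

    def test_disjoint_target_flags_unmapped(self, fitted_cohort):
        _, _, _, coll, _ = fitted_cohort
        mapped = map_gene_sets(coll, ["NOT_A_GENE"])
        assert all(not s.mapped for s in mapped.sets)

    def test_random_half_matches_set_arithmetic(self, fitted_cohort, rng):
        X, _, _, coll, _ = fitted_cohort
        target = list(rng.choice(X.gene_ids, size=X.n_genes // 2, replace=False))
        mapped = map_gene_sets(coll, target)
        tset = set(target)
        for ms, cs in zip(mapped.sets, coll):
            assert set(ms.retained_members) == set(cs.members) & tset
            assert ms.retained_fraction == pytest.approx(
                len(set(cs.members) & tset) / len(cs.members)
            )

    def test_idempotent(self, fitted_cohort, rng):
        X, _, _, coll, _ = fitted_cohort
        target = list(rng.choice(X.gene_ids, size=X.n_genes // 2, replace=False))
        once = map_gene_sets(coll, target)
        # mapping the retained members onto the same target changes nothing
        for ms in once.sets:
            again = set(ms.retained_members) & set(target)
            assert again == set(ms.retained_members)

    def test_empty_target_errors(self, fitted_cohort):
        _, _, _, coll, _ = fitted_cohort
        with pytest.raises(ValueError):
            map_gene_sets(coll, [])


class TestPAM:
    def test_two_pairs_hand_computed_silhouette(self):
        # pair structure on both set rows so it survives row standardisation
        pts = np.array([[0.0, 0.0], [0.5, 0.5], [10.0, 10.0], [10.5, 10.5]])
        S = _summary(pts.T)
        res = pam_cluster(S, 2)
        assert res.labels[0] == res.labels[1] != res.labels[2]
        assert res.labels[2] == res.labels[3]
        # hand silhouette on the standardised coordinates
        from cgsa.structure import _standardized_samples

        Xs = _standardized_samples(S)
        D = squareform(pdist(Xs))
        expected = []
        for i in range(4):
            same = [j for j in range(4) if res.labels[j] == res.labels[i] and j != i]
            other = [j for j in range(4) if res.labels[j] != res.labels[i]]
            a = np.mean(D[i, same])
            b = np.mean(D[i, other])
            expected.append((b - a) / max(a, b))
        np.testing.assert_allclose(res.silhouette, expected, atol=1e-10)

    def test_k_n_minus_one_single_pair(self, rng):
        pts = rng.normal(size=(5, 3)) * 5
        est = PAM(n_clusters=4).fit(pts)
        sizes = sorted(np.bincount(est.labels_))
        assert sizes == [1, 1, 1, 2]

    def test_matches_exhaustive_on_small_instances(self):
        r = np.random.default_rng(11)
        for _ in range(20):
            n = int(r.integers(6, 13))
            k = int(r.integers(2, 4))
            X = r.normal(size=(n, 2))
            D = squareform(pdist(X))
            est = PAM(n_clusters=k).fit(X)
            best = min(
                D[list(m)].min(axis=0).sum() for m in itertools.combinations(range(n), k)
            )
            assert est.inertia_ == pytest.approx(best, abs=1e-9)

    def test_swap_never_increases_cost(self):
        # moderate instance exercising the BUILD+SWAP path
        r = np.random.default_rng(12)
        X = np.vstack([r.normal(c, 1.0, size=(40, 4)) for c in (0, 4, 8)])
        from cgsa.structure import _pam_build, _pam_swap

        D = squareform(pdist(X))
        build = _pam_build(D, 3)
        cost_build = D[build].min(axis=0).sum()
        swapped = _pam_swap(D, build)
        cost_swap = D[swapped].min(axis=0).sum()
        assert cost_swap <= cost_build + 1e-9

    def test_infeasible_k_on_duplicates(self):
        pts = np.zeros((4, 2))
        with pytest.raises(ValueError):
            PAM(n_clusters=3).fit(pts)


class TestChooseK:
    def test_three_blobs_select_three(self, rng):
        centers = np.array([[0, 0], [6, 0], [0, 6]], dtype=float)
        pts = np.vstack([rng.normal(c, 1.0, size=(15, 2)) for c in centers])
        res = choose_k(_summary(pts.T), (2, 6))
        assert res.k == 3
        assert res.asw == max(res.asw_by_k.values())

    def test_single_blob_warns_low_asw(self, rng):
        pts = rng.normal(size=(40, 6))
        with pytest.warns(UserWarning, match="weak cluster structure"):
            res = choose_k(_summary(pts.T), (2, 5))
        assert all(v < 0.25 for v in res.asw_by_k.values())

    def test_asw_matches_independent_silhouette(self, rng):
        from sklearn.metrics import silhouette_score
        from cgsa.structure import _standardized_samples

        pts = np.vstack([rng.normal(0, 1, (12, 3)), rng.normal(5, 1, (12, 3))])
        S = _summary(pts.T)
        res = pam_cluster(S, 2)
        ref = silhouette_score(_standardized_samples(S), res.labels, metric="euclidean")
        assert res.asw == pytest.approx(ref, abs=1e-10)


class TestCentroidCorrelation:
    def test_self_correlation_diagonal_one(self, fitted_cohort, rng):
        _, _, _, _, S = fitted_cohort
        labels = rng.integers(0, 3, size=len(S.sample_ids))
        A = cluster_centroids(S, labels)
        C = centroid_correlation(A, A)
        np.testing.assert_allclose(np.diag(C.to_numpy()), 1.0, atol=1e-12)

    def test_proportional_profiles_correlate_one(self):
        import pandas as pd

        a = pd.DataFrame({"c1": [1.0, 2.0, 3.0, 4.0]}, index=list("wxyz"))
        b = pd.DataFrame({"d1": [2.0, 4.0, 6.0, 8.0]}, index=list("wxyz"))
        assert centroid_correlation(a, b).iloc[0, 0] == pytest.approx(1.0)

    def test_matches_direct_formula(self, rng):
        import pandas as pd

        A = pd.DataFrame(rng.normal(size=(8, 3)), index=[f"s{i}" for i in range(8)])
        B = pd.DataFrame(rng.normal(size=(8, 2)), index=[f"s{i}" for i in range(8)])
        C = centroid_correlation(A, B)
        for i in range(3):
            for j in range(2):
                expect = np.corrcoef(A.iloc[:, i], B.iloc[:, j])[0, 1]
                assert C.iloc[i, j] == pytest.approx(expect, abs=1e-12)

    def test_too_few_shared_sets_errors(self):
        import pandas as pd

        a = pd.DataFrame({"c": [1.0, 2.0]}, index=["s1", "s2"])
        with pytest.raises(ValueError, match="shared sets"):
            centroid_correlation(a, a)
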