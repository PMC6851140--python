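"""F_ST, Nei individual distances and classical-scaling PCoA."""

import numpy as np
import pytest

import dartsex as dx
from dartsex.calls import SnpCall

HOM_REF, HOM_ALT, HET = int(SnpCall.HOM_REF), int(SnpCall.HOM_ALT), int(SnpCall.HET)


def _matrix(rows, samples=None):
    rows = np.asarray(rows, dtype=np.int8)
    samples = samples or [f"s{i}" for i in range(rows.shape[1])]
    return dx.SnpMatrix([f"L{i}" for i in range(rows.shape[0])], samples, rows)


class TestFst:
    def test_opposite_fixation_is_one(self):
        matrix = _matrix([[HOM_REF, HOM_REF, HOM_ALT, HOM_ALT]] * 3)
        sites = {"s0": "A", "s1": "A", "s2": "B", "s3": "B"}
        pair, overall = dx.pairwise_fst(matrix, sites)
        assert pair.loc("A", "B") == pytest.approx(1.0)
        assert overall == pytest.approx(1.0)

    def test_identical_frequencies_zero(self):
        matrix = _matrix([[HET, HET, HET, HET]] * 2)
        sites = {"s0": "A", "s1": "A", "s2": "B", "s3": "B"}
        pair, overall = dx.pairwise_fst(matrix, sites)
        assert pair.loc("A", "B") == pytest.approx(0.0)
        assert overall == pytest.approx(0.0)

    def test_hand_example(self):
        # site A: two HOM_REF; site B: HOM_REF + HET -> F_ST = 1/7
        matrix = _matrix([[HOM_REF, HOM_REF, HOM_REF, HET]])
        sites = {"s0": "A", "s1": "A", "s2": "B", "s3": "B"}
        pair, _ = dx.pairwise_fst(matrix, sites)
        assert pair.loc("A", "B") == pytest.approx(0.142857, abs=1e-6)

    def test_bounds_and_locus_order_invariance(self):
        rng = np.random.default_rng(4)
        calls = rng.choice([HOM_REF, HET, HOM_ALT], size=(50, 12)).astype(np.int8)
        matrix = _matrix(calls)
        sites = {f"s{i}": ("A" if i < 6 else "B") for i in range(12)}
        pair, overall = dx.pairwise_fst(matrix, sites)
        assert 0.0 <= pair.loc("A", "B") <= 1.0
        assert 0.0 <= overall <= 1.0
        perm = rng.permutation(50)
        pair2, overall2 = dx.pairwise_fst(matrix.subset_loci(perm), sites)
        assert pair2.loc("A", "B") == pytest.approx(pair.loc("A", "B"))
        assert overall2 == pytest.approx(overall)

    def test_monomorphic_errors(self):
        matrix = _matrix([[HOM_REF, HOM_REF, HOM_REF, HOM_REF]])
        sites = {"s0": "A", "s1": "A", "s2": "B", "s3": "B"}
        with pytest.raises(ValueError, match="monomorphic"):
            dx.pairwise_fst(matrix, sites)

    def test_needs_two_sites(self):
        matrix = _matrix([[HOM_REF, HET]])
        with pytest.raises(ValueError, match="two sites"):
            dx.pairwise_fst(matrix, {"s0": "A", "s1": "A"})


class TestNeiDistance:
    def test_identical_individuals_zero(self):
        matrix = _matrix([[HET, HET], [HOM_REF, HOM_REF], [HOM_ALT, HOM_ALT]])
        dist = dx.nei_distance(matrix, list(matrix.locus_ids))
        assert dist.loc("s0", "s1") == 0.0

    def test_het_vs_homref_single_locus(self):
        matrix = _matrix([[HET, HOM_REF]])
        dist = dx.nei_distance(matrix, ["L0"])
        assert dist.loc("s0", "s1") == pytest.approx(0.34657, abs=1e-5)

    def test_female_block_identical(self, preset_sim, preset_results):
        """Females homozygous reference at all sex-linked loci are at
        pairwise distance zero."""
        res = preset_results
        females = [
            s
            for s in preset_sim.snp.sample_ids
            if res.augmented_registry.sex_of(s) == "F"
        ]
        block = [res.nei.loc(a, b) for a in females[:6] for b in females[:6]]
        assert max(block) == 0.0

    def test_symmetry_and_diagonal(self):
        rng = np.random.default_rng(6)
        calls = rng.choice([HOM_REF, HET, HOM_ALT, int(SnpCall.NULL)], size=(20, 8))
        dist = dx.nei_distance(_matrix(calls.astype(np.int8)), [f"L{i}" for i in range(20)])
        assert np.allclose(dist.values, dist.values.T)
        assert np.all(np.diag(dist.values) == 0)
        assert np.all(dist.values >= 0)

    def test_mismatch_monotonicity(self):
        # more opposite-homozygote loci -> larger distance
        base = [[HOM_REF, HOM_REF]] * 5
        one = [[HOM_REF, HOM_ALT]] + [[HOM_REF, HOM_REF]] * 4
        two = [[HOM_REF, HOM_ALT]] * 2 + [[HOM_REF, HOM_REF]] * 3
        d = [
            dx.nei_distance(_matrix(rows), [f"L{i}" for i in range(5)]).loc("s0", "s1")
            for rows in (base, one, two)
        ]
        assert d[0] < d[1] < d[2]

    def test_zero_identity_sentinel(self):
        matrix = _matrix([[HOM_REF, HOM_ALT]])
        with pytest.warns(UserWarning, match="sentinel"):
            dist = dx.nei_distance(matrix, ["L0"])
        assert dist.loc("s0", "s1") == dx.popgen.NEI_SENTINEL

    def test_null_loci_dropped_pairwise(self):
        rows = [[HET, int(SnpCall.NULL)], [HET, HET]]
        dist = dx.nei_distance(_matrix(rows), ["L0", "L1"])
        assert dist.loc("s0", "s1") == 0.0  # only L1 shared, identical there

    def test_feminised_y_males_closer_to_females(self, preset_sim, preset_results):
        """Low-heterozygosity males sit nearer the females than the fully
        heterozygous males in Nei distance over the sex-linked loci."""
        truth = preset_sim.truth
        res = preset_results
        females = list(
            truth.samples.loc[truth.samples["true_sex"] == "F", "sample_id"]
        )
        males1 = truth.lineage_members(1)
        males3 = truth.lineage_members(3)
        d_f = np.mean([res.nei.loc(a, b) for a in males3 for b in females])
        d_m1 = np.mean([res.nei.loc(a, b) for a in males3 for b in males1])
        assert d_f < d_m1


class TestPcoa:
    def test_two_points(self):
        d = 4.2
        dist = dx.DistanceMatrix(["a", "b"], np.array([[0.0, d], [d, 0.0]]))
        res = dx.pcoa(dist, k=1)
        assert sorted(res.coordinates[:, 0]) == pytest.approx([-d / 2, d / 2])

    def test_line_embedding_exact(self):
        x = np.array([0.0, 1.0, 3.0, 7.0])
        d = np.abs(x[:, None] - x[None, :])
        res = dx.pcoa(dx.DistanceMatrix(list("abcd"), d), k=1)
        recon = np.abs(res.coordinates[:, 0][:, None] - res.coordinates[:, 0][None, :])
        np.testing.assert_allclose(recon, d, atol=1e-10)

    def test_euclidean_cloud_reconstructed(self):
        rng = np.random.default_rng(12)
        points = rng.normal(size=(20, 3))
        d = np.linalg.norm(points[:, None] - points[None, :], axis=-1)
        res = dx.pcoa(dx.DistanceMatrix([str(i) for i in range(20)], d), k=3)
        recon = np.linalg.norm(
            res.coordinates[:, None] - res.coordinates[None, :], axis=-1
        )
        np.testing.assert_allclose(recon, d, atol=1e-8)

    def test_matches_skbio_oracle(self):
        skbio_ordination = pytest.importorskip("skbio.stats.ordination")
        rng = np.random.default_rng(13)
        points = rng.normal(size=(15, 4))
        d = np.linalg.norm(points[:, None] - points[None, :], axis=-1)
        ours = dx.pcoa(dx.DistanceMatrix([str(i) for i in range(15)], d), k=4)
        from skbio import DistanceMatrix as SkbioDM

        ref = skbio_ordination.pcoa(SkbioDM(d), number_of_dimensions=4)
        np.testing.assert_allclose(
            np.sort(ours.eigenvalues), np.sort(ref.eigvals.to_numpy()[:4]), atol=1e-8
        )
        np.testing.assert_allclose(
            np.abs(ours.coordinates), np.abs(ref.samples.to_numpy()[:, :4]), atol=1e-8
        )

    def test_truncation_warns(self):
        dist = dx.DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [1.0, 0.0]]))
        with pytest.warns(UserWarning, match="positive eigenvalue"):
            res = dx.pcoa(dist, k=5)
        assert res.coordinates.shape[1] == 1

    def test_coordinates_centred_and_sorted(self):
        rng = np.random.default_rng(14)
        points = rng.normal(size=(10, 3))
        d = np.linalg.norm(points[:, None] - points[None, :], axis=-1)
        res = dx.pcoa(dx.DistanceMatrix([str(i) for i in range(10)], d), k=3)
        np.testing.assert_allclose(res.coordinates.mean(axis=0), 0, atol=1e-10)
        assert np.all(np.diff(res.eigenvalues) <= 1e-12)
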