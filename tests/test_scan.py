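"""Concordance scoring, classification, system inference and the
spurious-linkage model."""

import numpy as np
import pytest

import dartsex as dx
from dartsex.calls import PaCall, SnpCall
from dartsex.scan import System

from conftest import snp_from_rows

HOM_REF, HOM_ALT, HET, NULL = (
    int(SnpCall.HOM_REF),
    int(SnpCall.HOM_ALT),
    int(SnpCall.HET),
    int(SnpCall.NULL),
)


class TestScoreSnpLocus:
    def test_perfect_locus_scores_two(self):
        calls = [HET] * 31 + [HOM_REF] * 13
        sexes = ["M"] * 31 + ["F"] * 13
        score = dx.score_snp_locus(calls, sexes, "XY")
        assert score.prop_het_heterogametic == 1.0
        assert score.prop_homref_homogametic == 1.0
        assert score.score == 2.0 and score.is_perfect

    def test_zw_hypothesis_is_mirror(self):
        calls = [HET] * 31 + [HOM_REF] * 13
        sexes = ["M"] * 31 + ["F"] * 13
        score = dx.score_snp_locus(calls, sexes, "ZW")
        assert score.prop_het_heterogametic == 0.0
        assert score.prop_homref_homogametic == 0.0
        assert score.score == 0.0

    def test_null_counts_against_denominator(self):
        calls = [HET] * 9 + [NULL] + [HOM_REF] * 10
        sexes = ["M"] * 10 + ["F"] * 10
        score = dx.score_snp_locus(calls, sexes, "XY")
        assert score.prop_het_heterogametic == pytest.approx(0.9)
        assert score.score == pytest.approx(1.9)

    def test_unknown_sex_excluded(self):
        calls = [HET, HET, HOM_ALT, HOM_REF, HOM_REF]
        sexes = ["M", "M", "U", "F", "F"]
        assert dx.score_snp_locus(calls, sexes, "XY").score == 2.0

    def test_single_sex_errors(self):
        with pytest.raises(ValueError, match="score undefined"):
            dx.score_snp_locus([HET, HET], ["M", "M"], "XY")


class TestScanSnp:
    def test_planted_recovery_zero_noise(self, small_params):
        # scan against the true sexes: masking a phenotype must not be able
        # to hide the planted classes
        sim = dx.simulate(small_params)
        scan = dx.scan_snp(sim.snp, sim.truth.true_registry())
        assert scan.perfect_xy == sim.truth.loci_of("PERFECT_SNP")
        assert scan.perfect_zw == []

    def test_label_swap_exchanges_systems(self, small_params):
        sim = dx.simulate(small_params)
        fwd = dx.scan_snp(sim.snp, sim.registry)
        rev = dx.scan_snp(sim.snp, sim.registry.swapped())
        assert rev.perfect_zw == fwd.perfect_xy
        assert rev.perfect_xy == fwd.perfect_zw
        np.testing.assert_array_equal(
            rev.zw["score"].to_numpy(), fwd.xy["score"].to_numpy()
        )

    def test_score_is_sum_of_proportions(self, small_params):
        sim = dx.simulate(small_params)
        table = dx.scan_snp(sim.snp, sim.registry).xy
        np.testing.assert_allclose(
            table["score"],
            table["prop_het_heterogametic"] + table["prop_homref_homogametic"],
        )

    def test_locus_permutation_invariance(self, small_params):
        sim = dx.simulate(small_params)
        perm = np.random.default_rng(0).permutation(sim.snp.n_loci)
        scan = dx.scan_snp(sim.snp.subset_loci(perm), sim.registry)
        base = dx.scan_snp(sim.snp, sim.registry)
        assert set(scan.perfect_xy) == set(base.perfect_xy)

    def test_no_spurious_perfect_loci_at_study_size(self):
        """Unlinked Hardy-Weinberg loci essentially never reach S=2 at n=44."""
        total = 0
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            calls, _ = dx.hardy_weinberg_snp(rng, 1000, 44)
            matrix = dx.SnpMatrix(
                [f"L{i}" for i in range(1000)], [f"s{i}" for i in range(44)], calls
            )
            registry = dx.SexRegistry(
                {f"s{i}": ("M" if i < 31 else "F") for i in range(44)}
            )
            total += len(dx.scan_snp(matrix, registry).perfect_xy)
        assert total <= 1


class TestPaScoring:
    def test_high_presence_with_nulls(self):
        calls = [int(PaCall.PRESENT)] * 49 + [int(PaCall.NULL)] + [int(PaCall.ABSENT)] * 13
        sexes = ["M"] * 50 + ["F"] * 13
        score = dx.score_pa_locus(calls, sexes, "XY")
        assert score.prop_present_heterogametic == pytest.approx(0.98)
        assert score.prop_null_heterogametic == pytest.approx(0.02)
        assert score.prop_absent_homogametic == 1.0
        assert score.contradiction_free

    def test_all_null_scores_zero(self):
        calls = [int(PaCall.NULL)] * 6
        score = dx.score_pa_locus(calls, ["M"] * 3 + ["F"] * 3, "XY")
        assert score.prop_present_heterogametic == 0.0
        assert score.prop_absent_homogametic == 0.0

    def test_single_present_female_breaks_contradiction_free(self):
        calls = [int(PaCall.PRESENT)] * 3 + [int(PaCall.PRESENT)] + [int(PaCall.ABSENT)] * 2
        sexes = ["M"] * 3 + ["F"] * 3
        assert not dx.score_pa_locus(calls, sexes, "XY").contradiction_free

    def test_scan_pa_ninety_percent_rule(self):
        # six Y-fragment-like loci: >=90% present in males, absent in females,
        # shortfalls only ever null
        rng = np.random.default_rng(3)
        n_m, n_f = 31, 13
        calls = np.full((6, n_m + n_f), int(PaCall.ABSENT), dtype=np.int8)
        calls[:, :n_m] = PaCall.PRESENT
        for i in range(6):
            nulls = rng.choice(n_m, size=rng.integers(0, 3), replace=False)
            calls[i, nulls] = PaCall.NULL
        samples = [f"s{i}" for i in range(n_m + n_f)]
        matrix = dx.PresenceMatrix([f"P{i}" for i in range(6)], samples, calls)
        registry = dx.SexRegistry(
            {s: ("M" if i < n_m else "F") for i, s in enumerate(samples)}
        )
        scan = dx.scan_pa(matrix, registry)
        assert scan.linked_xy == list(matrix.locus_ids)
        assert scan.linked_zw == []
        # full strictness excludes any locus with a null shortfall
        strict = dx.scan_pa(matrix, registry, min_prop=1.0)
        assert all(
            (calls[matrix.locus_index(x)] != PaCall.NULL).all()
            for x in strict.linked_xy
        )

    def test_planted_pa_recovery(self, small_params):
        sim = dx.simulate(small_params)
        scan = dx.scan_pa(sim.pa, sim.registry)
        assert scan.linked_xy == sim.truth.loci_of("PA_LINKED")
        assert scan.linked_zw == []


class TestModerateLoci:
    def test_partial_male_heterozygosity_included(self):
        row = [HET] * 13 + [HOM_REF] * 21 + [HOM_REF] * 18
        sexes = ["M"] * 34 + ["F"] * 18
        matrix, registry = snp_from_rows(row, sexes)
        assert dx.find_moderate_loci(matrix, registry, "XY") == ["L0"]

    def test_one_het_female_excludes(self):
        row = [HET] * 13 + [HOM_REF] * 21 + [HET] + [HOM_REF] * 17
        sexes = ["M"] * 34 + ["F"] * 18
        matrix, registry = snp_from_rows(row, sexes)
        assert dx.find_moderate_loci(matrix, registry, "XY") == []

    def test_null_female_excludes_by_default(self):
        row = [HET] * 13 + [HOM_REF] * 21 + [NULL] + [HOM_REF] * 17
        sexes = ["M"] * 34 + ["F"] * 18
        matrix, registry = snp_from_rows(row, sexes)
        assert dx.find_moderate_loci(matrix, registry, "XY") == []
        assert dx.find_moderate_loci(
            matrix, registry, "XY", allow_null_homogametic=True
        ) == ["L0"]

    def test_perfect_locus_excluded(self):
        row = [HET] * 34 + [HOM_REF] * 18
        sexes = ["M"] * 34 + ["F"] * 18
        matrix, registry = snp_from_rows(row, sexes)
        assert dx.find_moderate_loci(matrix, registry, "XY") == []

    def test_below_het_floor_excluded(self):
        row = [HET] * 2 + [HOM_REF] * 32 + [HOM_REF] * 18
        sexes = ["M"] * 34 + ["F"] * 18
        matrix, registry = snp_from_rows(row, sexes)
        assert dx.find_moderate_loci(matrix, registry, "XY", min_het_prop=0.25) == []


class TestInferSystem:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ((11, 0, 6, 0), System.XY),
            ((0, 11, 0, 6), System.ZW),
            ((0, 0, 0, 0), System.UNDETERMINED),
            ((3, 2, 0, 0), System.UNDETERMINED),
            ((0, 0, 1, 0), System.XY),
        ],
    )
    def test_rule(self, counts, expected):
        assert dx.infer_system(*counts) is expected


class TestSpuriousModel:
    @pytest.mark.parametrize("n,p", [(1, 0.5), (2, 0.25), (44, 5.6843e-14)])
    def test_probability(self, n, p):
        assert dx.spurious_probability(n) == pytest.approx(p, rel=1e-4)

    def test_expected_counts(self):
        assert dx.expected_spurious(20111, 44) == pytest.approx(1.14e-9, rel=5e-3)
        assert dx.expected_spurious(19121, 44) == pytest.approx(1.087e-9, rel=5e-3)
        assert dx.expected_spurious(0, 44) == 0.0

    @pytest.mark.parametrize("m,expected", [(20111, 15), (1, 1), (2, 2)])
    def test_min_sample_size(self, m, expected):
        n = dx.min_sample_size(m)
        assert n == expected
        assert dx.expected_spurious(m, n) < 1.0
        if n > 1:
            assert dx.expected_spurious(m, n - 1) >= 1.0

    def test_estimate_consistency(self):
        est = dx.SpuriousEstimate(n=44, m=20111)
        assert est.expected_spurious == est.m * est.p_per_locus


def test_permutation_null_brackets_model_scale():
    """At n=8 the observed rate of chance-perfect loci on unlinked loci
    agrees with a sex-label permutation oracle and sits within an order
    of magnitude of the 0.5^n model."""
    n_samples, n_loci, n_seeds = 8, 10_000, 20
    half = n_samples // 2
    observed = permuted = 0
    for seed in range(n_seeds):
        rng = np.random.default_rng(7000 + seed)
        calls, _ = dx.hardy_weinberg_snp(rng, n_loci, n_samples)
        males = np.zeros(n_samples, dtype=bool)
        males[:half] = True
        # implementation under test
        perfect = np.all(calls[:, males] == HET, axis=1) & np.all(
            calls[:, ~males] == HOM_REF, axis=1
        )
        observed += int(perfect.sum())
        # permutation oracle: same genotypes, shuffled labels
        shuffled = males[rng.permutation(n_samples)]
        perm_perfect = np.all(calls[:, shuffled] == HET, axis=1) & np.all(
            calls[:, ~shuffled] == HOM_REF, axis=1
        )
        permuted += int(perm_perfect.sum())
    total_loci = n_loci * n_seeds
    # binomial agreement between the two counts
    rate = (observed + permuted) / (2 * total_loci)
    se = np.sqrt(2 * total_loci * rate * (1 - rate))
    assert abs(observed - permuted) <= 5 * max(se, 1.0)
    model_expected = total_loci * dx.spurious_probability(n_samples)
    assert model_expected / 10 <= observed <= model_expected * 10
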