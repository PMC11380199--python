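"""Per-variant deltas and aggregate MAVE information scores."""

import math

import pytest

from maveinfo import (
    FunctionalClassMap,
    SyntheticMaveSpec,
    VariantEvidenceRecord,
    fold_increase,
    generate_synthetic_mave,
    mave_information_score,
    variant_info_delta,
)

# Independent oracle: direct formula evaluation with its own frozen odds,
# bypassing EvidenceOddsTable and the scoring pipeline entirely.
ORACLE_ODDS = {
    "PM2_supporting": 2.08,
    "BS3": 1 / 18.7,
    "PS3": 18.7,
    "PS": 18.7,
    "BM": 1 / 4.33,
    "PP": 2.08,
    "BP": 1 / 2.08,
}


def oracle_delta(prior, baseline_codes, mave_code):
    def info(p):
        if p in (0.0, 1.0):
            return 1.0
        return 1.0 + p * math.log2(p) + (1 - p) * math.log2(1 - p)

    def post(odds, pr):
        return odds * pr / ((odds - 1) * pr + 1)

    base = math.prod(ORACLE_ODDS[c] for c in baseline_codes)
    before = post(base, prior)
    after = post(base * (ORACLE_ODDS[mave_code] if mave_code else 1.0), prior)
    return info(after) - info(before)


class TestVariantInfoDelta:
    def test_brca1_functionally_normal(self, brca1_records):
        """PM2_supporting baseline plus BS3 gains 0.602 bits at prior 0.1."""
        res = variant_info_delta(brca1_records[0])
        assert res.posterior_before == pytest.approx(0.188, abs=5e-4)
        assert res.info_before == pytest.approx(0.303, abs=5e-4)
        assert res.posterior_after == pytest.approx(0.012, abs=5e-4)
        assert res.info_after == pytest.approx(0.905, abs=5e-3)
        assert res.delta_bits == pytest.approx(0.602, abs=5e-3)

    def test_brca1_loss_of_function_symmetry(self, brca1_records):
        """PS3 swings the posterior from 0.188 to 0.812 with zero net
        information change: the mirrored posterior carries the same
        certainty."""
        res = variant_info_delta(brca1_records[1])
        assert res.posterior_after == pytest.approx(0.812, abs=2e-3)
        assert res.info_after == pytest.approx(0.303, abs=2e-3)
        assert res.delta_bits == pytest.approx(0.000, abs=5e-3)

    def test_delta_consistent_with_info_fields(self, brca1_records):
        for rec in brca1_records:
            res = variant_info_delta(rec)
            assert res.delta_bits == pytest.approx(
                res.info_after - res.info_before, abs=1e-12
            )
            assert -1.0 <= res.delta_bits <= 1.0

    def test_tp53_per_class_deltas(self, tp53_class_map):
        """Benign-moderate normals gain ~0.30 bits; pathogenic-strong
        abnormals lose ~0.44 bits at the 0.1 prior."""
        normal = VariantEvidenceRecord("v1", functional_class="normal")
        abnormal = VariantEvidenceRecord("v2", functional_class="abnormal")
        assert variant_info_delta(normal, tp53_class_map).delta_bits == pytest.approx(
            0.30, abs=5e-3
        )
        assert variant_info_delta(abnormal, tp53_class_map).delta_bits == pytest.approx(
            -0.44, abs=5e-3
        )

    def test_intermediate_maps_to_no_evidence(self):
        rec = VariantEvidenceRecord("v", functional_class="intermediate")
        res = variant_info_delta(rec, FunctionalClassMap())
        assert res.delta_bits == 0.0
        assert res.posterior_before == res.posterior_after

    def test_odds_one_mave_code_gives_zero_delta(self):
        rec = VariantEvidenceRecord("v", mave_code="none", prior=0.3)
        assert variant_info_delta(rec).delta_bits == 0.0

    def test_record_without_evidence_rejected(self):
        rec = VariantEvidenceRecord("v")
        with pytest.raises(ValueError, match="neither"):
            variant_info_delta(rec)

    def test_matches_oracle_on_worked_examples(self, brca1_records):
        for rec in brca1_records:
            res = variant_info_delta(rec)
            assert res.delta_bits == pytest.approx(
                oracle_delta(0.1, rec.baseline_codes, rec.mave_code), abs=1e-12
            )


class TestMaveInformationScore:
    def test_absolute_mode_tp53_abnormal(self, tp53_class_map):
        """With no prior information (prior 0.5) a pathogenic-strong call
        contributes 0.71 bits."""
        rec = VariantEvidenceRecord("v", functional_class="abnormal")
        report = mave_information_score([rec], tp53_class_map, mode="absolute")
        assert report.total_bits == pytest.approx(0.71, abs=5e-3)
        assert report.absolute_bits == report.total_bits

    def test_relative_mode_tp53_normal(self, tp53_class_map):
        rec = VariantEvidenceRecord("v", functional_class="normal", prior=0.1)
        report = mave_information_score([rec], tp53_class_map, mode="relative")
        assert report.total_bits == pytest.approx(0.30, abs=5e-3)

    def test_duplication_scales_total_exactly(self, tp53_class_map):
        rec = VariantEvidenceRecord("v", functional_class="abnormal")
        one = mave_information_score([rec], tp53_class_map).total_bits
        seven = mave_information_score([rec] * 7, tp53_class_map).total_bits
        assert seven == pytest.approx(7 * one, abs=1e-12)

    def test_additivity_and_permutation_invariance(self, tp53_class_map):
        spec = SyntheticMaveSpec(
            n_normal=20, n_intermediate=5, n_abnormal=15, random_seed=11,
            baseline_code_frequency={"PM2_supporting": 0.4},
        )
        records = generate_synthetic_mave(spec)
        whole = mave_information_score(records, tp53_class_map)
        part1 = mave_information_score(records[:17], tp53_class_map)
        part2 = mave_information_score(records[17:], tp53_class_map)
        assert whole.total_bits == pytest.approx(
            part1.total_bits + part2.total_bits, abs=1e-9
        )
        shuffled = records[::-1]
        assert mave_information_score(
            shuffled, tp53_class_map
        ).total_bits == pytest.approx(whole.total_bits, abs=1e-12)

    def test_total_equals_sum_of_per_variant(self, tp53_class_map):
        records = generate_synthetic_mave(
            SyntheticMaveSpec(n_normal=30, n_abnormal=30, random_seed=3)
        )
        report = mave_information_score(records, tp53_class_map)
        assert report.total_bits == pytest.approx(
            sum(r.delta_bits for r in report.per_variant), abs=1e-9
        )

    def test_absolute_mode_nonnegative_relative_can_be_negative(self, tp53_class_map):
        records = generate_synthetic_mave(
            SyntheticMaveSpec(n_normal=0, n_abnormal=40, random_seed=5)
        )
        relative = mave_information_score(records, tp53_class_map, mode="relative")
        absolute = mave_information_score(records, tp53_class_map, mode="absolute")
        assert relative.total_bits < 0  # strong pathogenic vs 0.1 prior conflicts
        assert absolute.total_bits >= 0
        assert all(r.delta_bits >= 0 for r in absolute.per_variant)
        assert absolute.absolute_bits == pytest.approx(relative.absolute_bits)

    def test_oracle_equivalence_on_synthetic_cohort(self, tp53_class_map):
        """Report total matches an independent direct-formula summation."""
        spec = SyntheticMaveSpec(
            n_normal=40, n_intermediate=20, n_abnormal=40, random_seed=42,
            baseline_code_frequency={"PM2_supporting": 0.3, "PP": 0.1},
        )
        records = generate_synthetic_mave(spec)
        report = mave_information_score(records, tp53_class_map)
        class_codes = {"normal": "BM", "intermediate": None, "abnormal": "PS"}
        expected = math.fsum(
            oracle_delta(r.prior, r.baseline_codes, class_codes[r.functional_class])
            for r in records
        )
        assert report.total_bits == pytest.approx(expected, abs=1e-9)

    def test_intermediates_counted_but_contribute_nothing(self, tp53_class_map):
        records = generate_synthetic_mave(
            SyntheticMaveSpec(n_normal=4, n_intermediate=6, n_abnormal=0, random_seed=1)
        )
        report = mave_information_score(records, tp53_class_map)
        assert report.n_variants == 10
        zeroes = [r for r in report.per_variant if r.delta_bits == 0.0]
        assert len(zeroes) == 6

    def test_multi_substitution_records_excluded(self, tp53_class_map):
        keep = VariantEvidenceRecord("a", functional_class="normal")
        drop = VariantEvidenceRecord(
            "b", functional_class="normal", single_substitution=False
        )
        report = mave_information_score([keep, drop], tp53_class_map)
        assert report.n_variants == 1
        assert report.n_excluded_multi_substitution == 1
        assert report.total_bits == pytest.approx(
            mave_information_score([keep], tp53_class_map).total_bits
        )

    def test_vus_only_counts_reclassifications(self, tp53_class_map):
        """Only VUS-flagged records whose posterior reaches the
        likely-benign/likely-pathogenic bands enter vus_only_bits."""
        reclassified = VariantEvidenceRecord(
            "lb", functional_class="normal", is_vus=True
        )  # posterior 0.025 <= 0.10
        still_vus = VariantEvidenceRecord(
            "mid", functional_class="abnormal", is_vus=True
        )  # posterior 0.675, inside the VUS band
        unflagged = VariantEvidenceRecord("nf", functional_class="normal")
        report = mave_information_score(
            [reclassified, still_vus, unflagged], tp53_class_map
        )
        only = variant_info_delta(reclassified, tp53_class_map).delta_bits
        assert report.vus_only_bits == pytest.approx(only, abs=1e-12)

    def test_empty_inputs_rejected(self, tp53_class_map):
        with pytest.raises(ValueError):
            mave_information_score([], tp53_class_map)
        with pytest.raises(ValueError):
            mave_information_score(
                [
                    VariantEvidenceRecord(
                        "x", functional_class="normal", single_substitution=False
                    )
                ],
                tp53_class_map,
            )

    def test_brca1_cohort_reproduces_printed_total(self):
        """The BRCA1 saturation-editing composition (2821 normal, 249
        intermediate, 823 loss of function; BS3/PS3 weights, prior 0.1)
        yields the printed 813.2 bits."""
        spec = SyntheticMaveSpec(
            n_normal=2821,
            n_intermediate=249,
            n_abnormal=823,
            class_map=FunctionalClassMap(normal="BS3", abnormal="PS3"),
            prior=0.1,
            gene="BRCA1",
            random_seed=0,
        )
        records = generate_synthetic_mave(spec)
        report = mave_information_score(records, spec.class_map)
        assert report.n_variants == 3893
        assert report.total_bits == pytest.approx(813.2, rel=0.005)


class TestFoldIncrease:
    @pytest.mark.parametrize(
        "total, vus, expected, tol",
        [
            (813.2, 36.9, 22.0, 0.1),
            (893.6, 10.5, 85.1, 0.2),
            (160.0, 46.3, 3.5, 0.05),
            (7.7, 7.7, 1.0, 1e-12),
        ],
    )
    def test_table_values(self, total, vus, expected, tol):
        assert fold_increase(total, vus) == pytest.approx(expected, abs=tol)

    def test_nonpositive_denominator_not_computable(self):
        assert fold_increase(10.0, 0.0) is None
        assert fold_increase(10.0, -1.0) is None
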