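"""Variant QC rules, mean imputation and weighted burden scores."""

import numpy as np
import pytest

from rareburden import (
    GenotypeMatrix,
    GroupCounts,
    VariantAnnotation,
    VariantRecord,
    WeightScheme,
    combined_weight,
    filter_variants,
    gene_burden_scores,
    impute_missing,
)

ANN = VariantAnnotation("synonymous")


def rec(cases, controls, vid="1:100:A:G", ann=ANN):
    return VariantRecord.from_counts(vid, "G1", cases, controls, ann)


class TestFilterVariants:
    def test_excessive_missingness_excluded(self):
        # ~14% of pooled genotypes missing; otherwise the variant would be kept
        v = rec(GroupCounts(78, 2, 0, 20), GroupCounts(98, 2, 0, 10))
        kept, excluded = filter_variants([v])
        assert not kept
        assert excluded[0][1] == "missingness"

    def test_rare_in_one_group_is_kept(self):
        # maf 0.02 in cases, 0.005 in controls: rare in either group suffices
        v = rec(GroupCounts(96, 4, 0), GroupCounts(99, 1, 0))
        assert v.maf_cases == pytest.approx(0.02)
        assert v.maf_controls == pytest.approx(0.005)
        kept, _ = filter_variants([v])
        assert kept == [v]

    def test_common_in_both_groups_excluded(self):
        v = rec(GroupCounts(90, 10, 0), GroupCounts(92, 8, 0))
        kept, excluded = filter_variants([v])
        assert not kept
        assert excluded[0][1] == "maf"

    def test_pooled_het_deficit_excluded(self):
        # pooled het=1 < hom_ref=5 and < hom_alt=2
        v = rec(GroupCounts(3, 1, 1), GroupCounts(2, 0, 1))
        kept, excluded = filter_variants([v])
        assert not kept
        assert excluded[0][1] == "het_deficit"

    def test_empty_input(self):
        assert filter_variants([]) == ([], [])

    def test_idempotent(self):
        rng = np.random.default_rng(5)
        variants = [
            rec(
                GroupCounts(*rng.integers(0, 50, size=4)),
                GroupCounts(*rng.integers(0, 50, size=4)),
                vid=f"1:{i}:A:G",
            )
            for i in range(50)
        ]
        kept, _ = filter_variants(variants)
        kept_again, excluded_again = filter_variants(kept)
        assert kept_again == kept and not excluded_again


class TestImputeMissing:
    @pytest.mark.parametrize(
        "column, expected",
        [
            ([0, 1, 2, np.nan], [0, 1, 2, 1.0]),
            ([0, 0, np.nan, np.nan], [0, 0, 0, 0]),
        ],
    )
    def test_mean_fill(self, column, expected):
        assert impute_missing(np.array(column)) == pytest.approx(expected)

    def test_nine_observed_mean(self):
        col = np.array([1, 1, 1, 0, 0, 0, 0, 0, 0, np.nan])
        assert impute_missing(col)[-1] == pytest.approx(3 / 9)

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            impute_missing(np.array([np.nan, np.nan]))

    def test_column_mean_preserved(self):
        rng = np.random.default_rng(7)
        col = rng.integers(0, 3, 100).astype(float)
        col[rng.random(100) < 0.2] = np.nan
        observed_mean = np.nanmean(col)
        assert impute_missing(col).mean() == pytest.approx(observed_mean)


def _random_instance(rng, n_subjects=20, n_variants=5, missing=True):
    """Random matrix + matching records (cases = first half of subjects)."""
    dosages = rng.binomial(1, 0.05, size=(n_subjects, n_variants)).astype(float)
    if missing:
        dosages[rng.random(dosages.shape) < 0.05] = np.nan
    ids = [f"1:{i}:A:G" for i in range(n_variants)]
    subjects = [f"S{i}" for i in range(n_subjects)]
    gm = GenotypeMatrix(dosages, subjects, ids)
    case_mask = np.arange(n_subjects) < n_subjects // 2
    anns = [
        VariantAnnotation(rng.choice(["synonymous", "lof", "protein_altering"]))
        for _ in range(n_variants)
    ]
    records = [
        VariantRecord.from_counts(vid, "G1", *gm.tally(vid, case_mask), annotation=ann)
        for vid, ann in zip(ids, anns)
    ]
    return gm, records


def brute_force_scores(gm, records, scheme):
    """Independent double-loop implementation of the weighted burden score."""
    scores = []
    for s in range(gm.n_subjects):
        total = 0.0
        for v in records:
            col = gm.column(v.variant_id)
            if v.flipped:
                col = 2.0 - col
            g = col[s]
            if np.isnan(g):
                g = np.nanmean(col)
            maf = min(v.maf_overall, scheme.maf_cap)
            total += combined_weight(maf, v.annotation, scheme) * g
        scores.append(total)
    return np.array(scores)


class TestGeneBurdenScores:
    def test_matches_brute_force(self):
        scheme = WeightScheme()
        rng = np.random.default_rng(42)
        for _ in range(25):
            gm, records = _random_instance(rng)
            got = gene_burden_scores(gm, records, scheme)
            assert got == pytest.approx(brute_force_scores(gm, records, scheme), abs=1e-12)

    def test_variant_order_irrelevant(self):
        rng = np.random.default_rng(3)
        gm, records = _random_instance(rng, missing=False)
        forward = gene_burden_scores(gm, records)
        backward = gene_burden_scores(gm, records[::-1])
        assert forward == pytest.approx(backward)

    def test_linearity_in_allele_counts(self):
        rng = np.random.default_rng(4)
        gm, records = _random_instance(rng, missing=False)
        target = next(v for v in records if not v.flipped)
        j = gm.variant_ids.index(target.variant_id)
        s = int(np.argmin(gm.dosages[:, j]))  # a subject with a spare allele slot
        bumped = gm.dosages.copy()
        bumped[s, j] += 1
        before = gene_burden_scores(gm, records)
        after = gene_burden_scores(GenotypeMatrix(bumped, gm.subject_ids, gm.variant_ids), records)
        scheme = WeightScheme()
        w = combined_weight(min(target.maf_overall, 0.01), target.annotation, scheme)
        assert after[s] - before[s] == pytest.approx(w)
        mask = np.arange(gm.n_subjects) != s
        assert after[mask] == pytest.approx(before[mask])

    def test_zero_genotypes_zero_score(self):
        gm = GenotypeMatrix(np.zeros((4, 2)), list("abcd"), ["1:1:A:G", "1:2:A:G"])
        case = np.array([True, True, False, False])
        records = [
            VariantRecord.from_counts(v, "G1", *gm.tally(v, case), annotation=ANN)
            for v in gm.variant_ids
        ]
        assert gene_burden_scores(gm, records) == pytest.approx(np.zeros(4))

    def test_misaligned_variant_list_rejected(self):
        gm, records = _random_instance(np.random.default_rng(0), missing=False)
        ghost = VariantRecord.from_counts(
            "9:9:A:G", "G1", GroupCounts(9, 1, 0), GroupCounts(10, 0, 0), ANN
        )
        with pytest.raises(ValueError, match="absent"):
            gene_burden_scores(gm, records + [ghost])


def test_minor_allele_orientation():
    """Records with common alt alleles are flipped and scored on 2 - dosage."""
    dosages = np.array([[2.0], [2.0], [2.0], [1.0]])
    gm = GenotypeMatrix(dosages, list("abcd"), ["1:5:A:G"])
    case = np.array([True, True, False, False])
    v = VariantRecord.from_counts("1:5:A:G", "G1", *gm.tally("1:5:A:G", case), annotation=ANN)
    assert v.flipped
    assert v.maf_overall == pytest.approx(1 / 8)
    scores = gene_burden_scores(gm, [v])
    assert scores[3] > 0 and scores[:3] == pytest.approx(0.0)
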