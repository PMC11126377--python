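"""Disjoint category assignment, per-subject counts and the joint OR regression."""

import numpy as np
import pandas as pd
import pytest

from rareburden import (
    SimulationConfig,
    VariantAnnotation,
    assign_category,
    count_categories,
    crude_carrier_or,
    fit_category_regression,
    simulate_cohort,
)
from rareburden.categories import CATEGORY_ORDER
from rareburden.filtering import filter_variants


@pytest.mark.parametrize(
    "ann, expected",
    [
        (VariantAnnotation("lof"), "lof"),
        (VariantAnnotation("inframe_indel"), "inframe_indel"),
        (VariantAnnotation("synonymous"), "synonymous"),
        (VariantAnnotation("splice_region"), "splice_region"),
        (VariantAnnotation("protein_altering"), "protein_altering"),
        (VariantAnnotation("protein_altering", sift="deleterious"), "sift_deleterious"),
        (
            VariantAnnotation("protein_altering", polyphen="possibly_damaging"),
            "polyphen_possibly",
        ),
        # PolyPhen outranks SIFT when both flag the same variant
        (
            VariantAnnotation(
                "protein_altering", polyphen="probably_damaging", sift="deleterious"
            ),
            "polyphen_probably",
        ),
    ],
)
def test_assign_category_severity_ladder(ann, expected):
    assert assign_category(ann) == expected


def test_count_categories_matches_brute_force(small_sim):
    kept, _ = filter_variants(small_sim.variants)
    counts = count_categories(small_sim.genotypes, kept)
    # independent tally: loop subjects x variants with mean imputation
    gm = small_sim.genotypes
    expected = pd.DataFrame(0.0, index=gm.subject_ids, columns=list(CATEGORY_ORDER))
    for v in kept:
        col = gm.column(v.variant_id)
        if v.flipped:
            col = 2.0 - col
        fill = np.nanmean(col)
        j = expected.columns.get_loc(assign_category(v.annotation))
        for s, g in enumerate(col):
            expected.iloc[s, j] += fill if np.isnan(g) else g
    pd.testing.assert_frame_equal(counts, expected, check_exact=False, atol=1e-12)


def test_category_counts_are_disjoint_and_complete(small_sim):
    kept, _ = filter_variants(small_sim.variants)
    counts = count_categories(small_sim.genotypes, kept)
    gm = small_sim.genotypes.subset([v.variant_id for v in kept])
    dosages = gm.dosages.copy()
    for j, v in enumerate(kept):
        col = dosages[:, j]
        if v.flipped:
            col = 2.0 - col
        col[np.isnan(col)] = np.nanmean(col)
        dosages[:, j] = col
    assert counts.sum(axis=1).to_numpy() == pytest.approx(dosages.sum(axis=1))


class TestCrudeCarrierOr:
    def test_published_style_two_by_two(self):
        assert crude_carrier_or(97, 106091, 16, 363674) == pytest.approx(20.80, abs=0.005)

    @pytest.mark.parametrize(
        "args, expected",
        [((10, 100, 10, 100), 1.0), ((20, 120, 5, 105), 4.0)],
    )
    def test_simple_tables(self, args, expected):
        assert crude_carrier_or(*args) == pytest.approx(expected)

    def test_zero_cell_rejected(self):
        with pytest.raises(ValueError, match="zero cell"):
            crude_carrier_or(0, 100, 5, 100)

    def test_carriers_cannot_exceed_group(self):
        with pytest.raises(ValueError, match="exceed"):
            crude_carrier_or(101, 100, 5, 100)


def _recovery_sim(seed, log_or):
    config = SimulationConfig(
        n_subjects=20_000,
        mean_variants_per_gene=40,
        maf_log10_range=(-3.2, -2.0),
        category_probabilities={"lof": 0.25, "protein_altering": 0.35, "synonymous": 0.4},
        per_category_log_or={"lof": log_or},
        missing_rate=0.01,
        seed=seed,
    )
    sim = simulate_cohort(config)
    kept, _ = filter_variants(sim.variants)
    counts = count_categories(sim.genotypes, kept)
    results = fit_category_regression(counts, sim.cohort, kept)
    return {r.category: r for r in results}


def test_null_categories_have_ci_covering_one():
    by_cat = _recovery_sim(seed=21, log_or=0.0)
    active = [r for r in by_cat.values() if np.isfinite(r.or_estimate)]
    assert len(active) >= 3
    covering = [r for r in active if r.ci_low <= 1.0 <= r.ci_high]
    assert len(covering) == len(active)  # all null here; coverage expected


def test_protective_lof_effect_recovered():
    by_cat = _recovery_sim(seed=22, log_or=float(np.log(0.5)))
    lof = by_cat["lof"]
    assert lof.ci_low <= 0.5 <= lof.ci_high
    assert lof.or_estimate < 1 and lof.wald_slp < 0


def test_wald_slp_sign_matches_or_side(small_sim):
    kept, _ = filter_variants(small_sim.variants)
    counts = count_categories(small_sim.genotypes, kept)
    for r in fit_category_regression(counts, small_sim.cohort, kept):
        if not np.isfinite(r.or_estimate):
            continue
        assert r.ci_low <= r.or_estimate <= r.ci_high
        if r.or_estimate > 1:
            assert r.wald_slp >= 0
        elif r.or_estimate < 1:
            assert r.wald_slp <= 0


def test_zero_variance_category_reported_blank(small_sim):
    kept, _ = filter_variants(small_sim.variants)
    counts = count_categories(small_sim.genotypes, kept)
    counts["inframe_indel"] = 0.0
    results = {r.category: r for r in fit_category_regression(counts, small_sim.cohort, kept)}
    empty = results["inframe_indel"]
    assert np.isnan(empty.or_estimate) and empty.note == "zero_variance"
    assert empty.wald_slp == 0.0


def test_counts_misaligned_with_cohort_rejected(small_sim):
    kept, _ = filter_variants(small_sim.variants)
    counts = count_categories(small_sim.genotypes, kept)
    with pytest.raises(ValueError, match="aligned"):
        fit_category_regression(counts.iloc[:-1], small_sim.cohort, kept)
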