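"""Synthetic case-control cohorts for exercising the burden pipeline.

Real exome cohorts of the kind this package analyses are access-controlled,
so every stage is tested against simulated data with the same statistical
structure: rare biallelic variants (MAF <= 0.01) with Hardy-Weinberg
genotypes, functional categories drawn with realistic relative abundances
(intronic variants vastly outnumber loss-of-function ones), genotypes
missing at random, sex and 20 standard-normal ancestry covariates, and a
prospective logistic disease model

    logit P(case) = baseline + sum_c log_OR_c * count_c
                    + beta_sex * sex + sum_k beta_k * pc_k

where count_c is the subject's true allele count in variant category c.
The default baseline targets ~22.6% prevalence, the hyperlipidaemia rate in
the cohort this emulates. All randomness flows through one seeded
numpy Generator, so identical seeds give bit-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .association import N_PCS, CohortTable, ConvergenceError, fit_burden_lrt, fit_null_model
from .categories import CATEGORY_ORDER, assign_category
from .filtering import GenotypeMatrix, VariantRecord, filter_variants, gene_burden_scores
from .weights import VariantAnnotation, WeightScheme

__all__ = [
    "SimulationConfig",
    "SimulatedCohort",
    "NullCalibration",
    "simulate_cohort",
    "simulate_null_slp_distribution",
]

#: Relative abundance of the disjoint reporting categories, proportional to
#: per-gene variant counts typical of a large exome cohort (intronic >>
#: nonsynonymous >> LOF; indels rarest).
DEFAULT_CATEGORY_WEIGHTS = {
    "intronic_etc": 1116,
    "utr5": 46,
    "synonymous": 283,
    "splice_region": 81,
    "utr3": 27,
    "protein_altering": 624,
    "inframe_indel": 6,
    "lof": 44,
    "sift_deleterious": 329,
    "polyphen_possibly": 123,
    "polyphen_probably": 197,
}

#: ~22.6% prevalence (106,091 cases / 469,765 participants).
DEFAULT_PREVALENCE = 106091 / 469765

#: How each reporting category is realised as a variant annotation.
_CATEGORY_TO_ANNOTATION = {
    "sift_deleterious": VariantAnnotation("protein_altering", sift="deleterious"),
    "polyphen_possibly": VariantAnnotation("protein_altering", polyphen="possibly_damaging"),
    "polyphen_probably": VariantAnnotation("protein_altering", polyphen="probably_damaging"),
}


def _annotation_for(category: str) -> VariantAnnotation:
    if category in _CATEGORY_TO_ANNOTATION:
        return _CATEGORY_TO_ANNOTATION[category]
    return VariantAnnotation(category)


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the cohort generator; defaults are the study conditions."""

    n_subjects: int = 10_000
    n_genes: int = 1
    mean_variants_per_gene: float = 50.0
    maf_log10_range: tuple[float, float] = (-4.0, -2.0)  # log-uniform, cap 0.01
    category_probabilities: dict[str, float] = field(
        default_factory=lambda: _normalise(DEFAULT_CATEGORY_WEIGHTS)
    )
    per_category_log_or: dict[str, float] = field(default_factory=dict)
    baseline_log_odds: float = float(np.log(DEFAULT_PREVALENCE / (1 - DEFAULT_PREVALENCE)))
    sex_effect: float = 0.0
    pc_effects: tuple[float, ...] = (0.0,) * N_PCS
    missing_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2 or self.n_genes < 0:
            raise ValueError("need at least 2 subjects and a non-negative gene count")
        if not np.isclose(sum(self.category_probabilities.values()), 1.0):
            raise ValueError("category probabilities must sum to 1")
        unknown = set(self.category_probabilities) - set(CATEGORY_ORDER)
        if unknown:
            raise ValueError(f"unknown categories in probabilities: {sorted(unknown)}")
        if set(self.per_category_log_or) - set(CATEGORY_ORDER):
            raise ValueError("per_category_log_or keys must be reporting categories")
        if not 0 <= self.missing_rate < 0.5:
            raise ValueError("missing_rate must be in [0, 0.5)")
        lo, hi = self.maf_log10_range
        if lo >= hi or 10**hi > 0.01 + 1e-12:
            raise ValueError("maf_log10_range must be increasing with upper MAF <= 0.01")
        if len(self.pc_effects) != N_PCS:
            raise ValueError(f"pc_effects must have length {N_PCS}")


def _normalise(weights: dict[str, float]) -> dict[str, float]:
    total = sum(weights.values())
    return {k: v / total for k, v in weights.items()}


@dataclass
class SimulatedCohort:
    genotypes: GenotypeMatrix          # with missingness applied
    variants: list[VariantRecord]
    cohort: CohortTable
    truth: dict                        # per-variant maf/category, per-category log-ORs


def _draw_gene(
    config: SimulationConfig, rng: np.random.Generator, gene: str, chrom_pos0: int
) -> tuple[np.ndarray, list[str], list[VariantAnnotation], np.ndarray, list[str]]:
    """True (unmasked) dosages plus ids/annotations/MAFs for one gene."""
    n_var = max(1, int(rng.poisson(config.mean_variants_per_gene)))
    lo, hi = config.maf_log10_range
    mafs = 10 ** rng.uniform(lo, hi, size=n_var)
    cats = list(config.category_probabilities)
    probs = np.array([config.category_probabilities[c] for c in cats])
    drawn = rng.choice(len(cats), size=n_var, p=probs)
    categories = [cats[i] for i in drawn]
    annotations = [_annotation_for(c) for c in categories]
    # HWE genotypes: dosage ~ Binomial(2, maf)
    dosages = rng.binomial(2, mafs, size=(config.n_subjects, n_var)).astype(float)
    ids = [f"1:{chrom_pos0 + 10 * i}:A:G" for i in range(n_var)]
    return dosages, ids, annotations, mafs, categories


def _covariates(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    sex = rng.integers(0, 2, size=config.n_subjects).astype(float)
    pcs = rng.standard_normal((config.n_subjects, N_PCS))
    return np.column_stack([sex, pcs])


def _phenotype(
    config: SimulationConfig,
    rng: np.random.Generator,
    covariates: np.ndarray,
    category_counts: np.ndarray,
    categories_in_order: list[str],
) -> np.ndarray:
    eta = np.full(config.n_subjects, config.baseline_log_odds)
    for j, cat in enumerate(categories_in_order):
        beta = config.per_category_log_or.get(cat, 0.0)
        if beta:
            eta += beta * category_counts[:, j]
    eta += config.sex_effect * covariates[:, 0]
    eta += covariates[:, 1:] @ np.asarray(config.pc_effects)
    return (rng.random(config.n_subjects) < 1.0 / (1.0 + np.exp(-eta))).astype(int)


def _mask_missing(
    dosages: np.ndarray, rate: float, rng: np.random.Generator
) -> np.ndarray:
    if rate <= 0:
        return dosages
    masked = dosages.copy()
    masked[rng.random(dosages.shape) < rate] = np.nan
    return masked


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Draw a full cohort: genotypes, variant records, phenotypes, truth log.

    Genotypes are drawn per variant under HWE at its drawn MAF; the phenotype
    is assigned prospectively from the *true* (pre-masking) category counts;
    missingness is then applied and per-group tallies computed on what an
    analyst would observe.
    """
    rng = np.random.default_rng(config.seed)
    covariates = _covariates(config, rng)

    all_dosage, all_ids, all_ann, all_maf, all_cat, all_gene = [], [], [], [], [], []
    for g in range(config.n_genes):
        gene = f"GENE{g + 1}"
        dos, ids, anns, mafs, cats = _draw_gene(config, rng, gene, 1_000_000 * (g + 1))
        all_dosage.append(dos)
        all_ids.extend(ids)
        all_ann.extend(anns)
        all_maf.extend(mafs)
        all_cat.extend(cats)
        all_gene.extend([gene] * len(ids))
    dosages = (
        np.concatenate(all_dosage, axis=1)
        if all_dosage
        else np.empty((config.n_subjects, 0))
    )

    cat_index = {c: j for j, c in enumerate(CATEGORY_ORDER)}
    counts = np.zeros((config.n_subjects, len(CATEGORY_ORDER)))
    for col, cat in enumerate(all_cat):
        counts[:, cat_index[cat]] += dosages[:, col]
    phenotype = _phenotype(config, rng, covariates, counts, list(CATEGORY_ORDER))

    masked = _mask_missing(dosages, config.missing_rate, rng)
    subject_ids = [f"S{i:06d}" for i in range(config.n_subjects)]
    genotypes = GenotypeMatrix(masked, subject_ids, all_ids)
    cohort = CohortTable(subject_ids, phenotype, covariates)

    case = cohort.case_mask
    variants = [
        VariantRecord.from_counts(
            vid, gene, *genotypes.tally(vid, case), annotation=ann
        )
        for vid, gene, ann in zip(all_ids, all_gene, all_ann)
    ]
    truth = {
        "maf": np.array(all_maf),
        "category": list(all_cat),
        "gene": list(all_gene),
        "per_category_log_or": {
            c: config.per_category_log_or.get(c, 0.0) for c in CATEGORY_ORDER
        },
    }
    return SimulatedCohort(genotypes, variants, cohort, truth)


@dataclass
class NullCalibration:
    """Empirical SLP sample from repeated null-gene analyses."""

    slps: np.ndarray
    n_failures: int

    def tail_probability(self, threshold: float) -> float:
        if self.slps.size == 0:
            return float("nan")
        return float(np.mean(np.abs(self.slps) >= threshold))

    def summary(self) -> dict[float, float]:
        return {t: self.tail_probability(t) for t in (1.0, 2.0, 3.0)}


def simulate_null_slp_distribution(
    config: SimulationConfig,
    n_replicates: int,
    scheme: WeightScheme | None = None,
) -> NullCalibration:
    """Run the full per-gene pipeline on null genes and collect SLPs.

    The cohort (covariates + phenotype) is drawn once under the null; each
    replicate then draws an independent gene, applies the variant filters,
    builds burden scores and runs the LRT. With well-calibrated tests
    P(|SLP| >= x) ~= 10**-x. Fit failures are counted, not fatal.
    """
    if any(v != 0.0 for v in config.per_category_log_or.values()):
        raise ValueError("null calibration requires all per-category effects zero")
    if n_replicates == 0:
        return NullCalibration(np.empty(0), 0)
    scheme = scheme or WeightScheme()
    rng = np.random.default_rng(config.seed)
    covariates = _covariates(config, rng)
    zero_counts = np.zeros((config.n_subjects, len(CATEGORY_ORDER)))
    phenotype = _phenotype(config, rng, covariates, zero_counts, list(CATEGORY_ORDER))
    subject_ids = [f"S{i:06d}" for i in range(config.n_subjects)]
    cohort = CohortTable(subject_ids, phenotype, covariates)
    null_res = fit_null_model(cohort)
    case = cohort.case_mask

    slps, failures = [], 0
    for rep in range(n_replicates):
        dos, ids, anns, _, _ = _draw_gene(config, rng, f"NULL{rep}", 1_000_000)
        masked = _mask_missing(dos, config.missing_rate, rng)
        genotypes = GenotypeMatrix(masked, subject_ids, ids)
        records = [
            VariantRecord.from_counts(vid, f"NULL{rep}", *genotypes.tally(vid, case), annotation=ann)
            for vid, ann in zip(ids, anns)
        ]
        kept, _ = filter_variants(records)
        if not kept:
            continue
        scores = gene_burden_scores(genotypes, kept, scheme)
        try:
            result = fit_burden_lrt(
                scores, cohort, gene=f"NULL{rep}", n_variants_kept=len(kept),
                null_result=null_res,
            )
        except ConvergenceError:
            failures += 1
            continue
        slps.append(result.slp)
    return NullCalibration(np.array(slps), failures)
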