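"""Variant-category decomposition of a gene's association signal.

Each kept variant is assigned to exactly one broad annotation category
(severity ladder below, most severe wins), per-subject allele counts are
tallied per category, and all category counts enter one joint logistic
regression with sex and 20 PCs as covariates. Per-category odds ratios,
Wald 95% CIs and signed log10 p-values quantify which kinds of variant
drive the gene's signal — e.g. whether loss-of-function variants raise or
lower risk relative to ordinary nonsynonymous ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from scipy import stats

from .association import CohortTable, ConvergenceError
from .filtering import GenotypeMatrix, VariantRecord, impute_missing
from .weights import VariantAnnotation

__all__ = [
    "CATEGORY_LADDER",
    "CATEGORY_LABELS",
    "CategoryResult",
    "assign_category",
    "count_categories",
    "fit_category_regression",
    "crude_carrier_or",
]

#: Disjoint reporting categories, most severe first. A nonsynonymous variant
#: flagged by PolyPhen outranks a SIFT-only flag; LOF and inframe indels
#: outrank everything.
CATEGORY_LADDER = (
    "lof",
    "inframe_indel",
    "polyphen_probably",
    "polyphen_possibly",
    "sift_deleterious",
    "protein_altering",
    "splice_region",
    "utr5",
    "utr3",
    "synonymous",
    "intronic_etc",
)

#: Human-readable labels used in result tables.
CATEGORY_LABELS = {
    "intronic_etc": "Intronic, etc",
    "utr5": "5 prime UTR",
    "synonymous": "Synonymous",
    "splice_region": "Splice region",
    "utr3": "3 prime UTR",
    "protein_altering": "Protein altering",
    "inframe_indel": "Indel, etc",
    "lof": "LOF",
    "sift_deleterious": "SIFT deleterious",
    "polyphen_possibly": "PolyPhen possibly damaging",
    "polyphen_probably": "PolyPhen probably damaging",
}

#: Table row order (mildest to most severe, modifiers last).
CATEGORY_ORDER = (
    "intronic_etc",
    "utr5",
    "synonymous",
    "splice_region",
    "utr3",
    "protein_altering",
    "inframe_indel",
    "lof",
    "sift_deleterious",
    "polyphen_possibly",
    "polyphen_probably",
)


@dataclass(frozen=True)
class CategoryResult:
    category: str
    n_variants: int
    total_count_controls: float
    mean_count_controls: float
    total_count_cases: float
    mean_count_cases: float
    or_estimate: float  # NaN when the category was dropped from the fit
    ci_low: float
    ci_high: float
    wald_slp: float
    note: str = ""


def assign_category(ann: VariantAnnotation) -> str:
    """Map an annotation to its single reporting category.

    Nonsynonymous variants flagged by PolyPhen or SIFT move into the
    corresponding modifier category so the counts stay disjoint.
    """
    if ann.category == "protein_altering":
        if ann.polyphen == "probably_damaging":
            return "polyphen_probably"
        if ann.polyphen == "possibly_damaging":
            return "polyphen_possibly"
        if ann.sift == "deleterious":
            return "sift_deleterious"
        return "protein_altering"
    if ann.category in CATEGORY_LADDER:
        return ann.category
    warnings.warn(f"unknown category {ann.category!r}; counting as intronic_etc")
    return "intronic_etc"


def count_categories(
    genotypes: GenotypeMatrix, variants: list[VariantRecord]
) -> pd.DataFrame:
    """Subjects x categories matrix of (imputed) minor-allele counts.

    Every variant contributes to exactly one category, so row sums equal the
    subject's total qualifying allele count.
    """
    counts = pd.DataFrame(
        0.0, index=genotypes.subject_ids, columns=list(CATEGORY_ORDER)
    )
    for v in variants:
        col = genotypes.column(v.variant_id)
        if v.flipped:
            col = 2.0 - col
        if np.isnan(col).any():
            col = impute_missing(col)
        counts[assign_category(v.annotation)] += col
    return counts


def _variants_per_category(variants: list[VariantRecord]) -> dict[str, int]:
    out = {c: 0 for c in CATEGORY_ORDER}
    for v in variants:
        out[assign_category(v.annotation)] += 1
    return out


def fit_category_regression(
    counts: pd.DataFrame,
    cohort: CohortTable,
    variants: list[VariantRecord] | None = None,
) -> list[CategoryResult]:
    """Joint logistic regression of case status on all category counts.

    Categories with zero variance carry no information; they are dropped
    from the design and reported with NaN OR (their table cells stay blank),
    mirroring how empty categories appear in practice. OR = exp(beta),
    CI = exp(beta +/- 1.96 SE), Wald p from (beta/SE)^2 on chi-square 1 df.
    """
    if counts.shape[0] != cohort.n_subjects:
        raise ValueError("category counts are not aligned with the cohort")
    n_variants = _variants_per_category(variants) if variants is not None else {}
    case = cohort.case_mask
    active = [c for c in counts.columns if np.ptp(counts[c].to_numpy()) > 0]
    if not active:
        raise ValueError("no category has non-zero variance; nothing to fit")

    X = sm.add_constant(
        np.column_stack([counts[active].to_numpy(), cohort.covariates]),
        has_constant="add",
    )
    from .association import _fit_logit

    res = _fit_logit(cohort.phenotype, X, "category regression")

    results = []
    for cat in counts.columns:
        col = counts[cat].to_numpy()
        base = dict(
            category=cat,
            n_variants=n_variants.get(cat, 0),
            total_count_controls=float(col[~case].sum()),
            mean_count_controls=float(col[~case].mean()),
            total_count_cases=float(col[case].sum()),
            mean_count_cases=float(col[case].mean()),
        )
        if cat not in active:
            results.append(
                CategoryResult(
                    **base,
                    or_estimate=float("nan"),
                    ci_low=float("nan"),
                    ci_high=float("nan"),
                    wald_slp=0.0,
                    note="zero_variance",
                )
            )
            continue
        i = 1 + active.index(cat)  # constant first
        beta, se = float(res.params[i]), float(res.bse[i])
        wald = (beta / se) ** 2 if se > 0 else 0.0
        p = float(stats.chi2.sf(wald, df=1))
        slp = 0.0 if p >= 1.0 or beta == 0.0 else float(-np.log10(p)) * np.sign(beta)
        with np.errstate(over="ignore"):  # huge SE on a near-empty category
            results.append(
                CategoryResult(
                    **base,
                    or_estimate=float(np.exp(beta)),
                    ci_low=float(np.exp(beta - 1.96 * se)),
                    ci_high=float(np.exp(beta + 1.96 * se)),
                    wald_slp=float(slp),
                )
            )
    return results


def crude_carrier_or(
    carriers_cases: int, n_cases: int, carriers_controls: int, n_controls: int
) -> float:
    """Unadjusted 2x2 carrier odds ratio (ad/bc); a sanity oracle, not the test.

    Raises on a zero cell: continuity corrections are deliberately out of
    scope, pick a bigger stratum instead.
    """
    for name, value in (
        ("carriers_cases", carriers_cases),
        ("n_cases", n_cases),
        ("carriers_controls", carriers_controls),
        ("n_controls", n_controls),
    ):
        if value < 0:
            raise ValueError(f"{name} must be non-negative")
    if carriers_cases > n_cases or carriers_controls > n_controls:
        raise ValueError("carrier count exceeds group size")
    a, b = carriers_cases, n_cases - carriers_cases
    c, d = carriers_controls, n_controls - carriers_controls
    if 0 in (a, b, c, d):
        raise ValueError(
            "zero cell in the 2x2 table; continuity corrections are out of scope"
        )
    return (a / b) / (c / d)
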