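"""Variant QC, missing-genotype imputation and gene-wise burden scores.

A variant qualifies for the burden score when

* its MAF is <= the rarity cutoff (0.01) in cases, in controls, or both;
* no more than 10% of genotypes are missing in the pooled sample;
* the pooled heterozygote count is not smaller than both homozygote counts
  (a crude guard against genotyping artefacts at ill-behaved sites).

Missing genotypes at kept variants are imputed to the per-variant mean
alternate-allele count over genotyped subjects; each subject's gene-wise
burden score is then the weighted sum of their (possibly fractional) allele
counts, weights from :mod:`rareburden.weights`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .weights import VariantAnnotation, WeightScheme, combined_weight

__all__ = [
    "GroupCounts",
    "VariantRecord",
    "GenotypeMatrix",
    "filter_variants",
    "impute_missing",
    "gene_burden_scores",
]

MAF_CUTOFF = 0.01
MAX_MISSING_FRACTION = 0.10


@dataclass(frozen=True)
class GroupCounts:
    """Genotype tallies within one phenotype group."""

    hom_ref: int
    het: int
    hom_alt: int
    missing: int = 0

    def __post_init__(self) -> None:
        if min(self.hom_ref, self.het, self.hom_alt, self.missing) < 0:
            raise ValueError("genotype counts must be non-negative")

    @property
    def n_genotyped(self) -> int:
        return self.hom_ref + self.het + self.hom_alt

    @property
    def n_total(self) -> int:
        return self.n_genotyped + self.missing

    @property
    def alt_freq(self) -> float:
        n = self.n_genotyped
        return (self.het + 2 * self.hom_alt) / (2 * n) if n else float("nan")


@dataclass(frozen=True)
class VariantRecord:
    """One biallelic site with per-group tallies and functional annotation.

    Allele frequencies are oriented to the pooled minor allele: if the
    alternate allele has pooled frequency > 0.5 the record is flipped (see
    :meth:`from_counts`), so ``maf_overall`` <= 0.5 always.
    """

    variant_id: str
    gene: str
    cases: GroupCounts
    controls: GroupCounts
    annotation: VariantAnnotation
    flipped: bool = False

    @property
    def maf_cases(self) -> float:
        return self.cases.alt_freq

    @property
    def maf_controls(self) -> float:
        return self.controls.alt_freq

    @property
    def maf_overall(self) -> float:
        n = self.cases.n_genotyped + self.controls.n_genotyped
        alt = (
            self.cases.het
            + 2 * self.cases.hom_alt
            + self.controls.het
            + 2 * self.controls.hom_alt
        )
        return alt / (2 * n) if n else float("nan")

    @property
    def missing_fraction(self) -> float:
        n = self.cases.n_total + self.controls.n_total
        return (self.cases.missing + self.controls.missing) / n if n else float("nan")

    @classmethod
    def from_counts(
        cls,
        variant_id: str,
        gene: str,
        cases: GroupCounts,
        controls: GroupCounts,
        annotation: VariantAnnotation,
    ) -> "VariantRecord":
        """Build a record, flipping to the pooled minor allele if needed."""
        rec = cls(variant_id, gene, cases, controls, annotation)
        if rec.maf_overall > 0.5:
            rec = cls(
                variant_id,
                gene,
                GroupCounts(cases.hom_alt, cases.het, cases.hom_ref, cases.missing),
                GroupCounts(
                    controls.hom_alt, controls.het, controls.hom_ref, controls.missing
                ),
                annotation,
                flipped=True,
            )
        return rec


class GenotypeMatrix:
    """Subjects x variants alternate-allele dosages; NaN marks missing calls."""

    def __init__(
        self,
        dosages: np.ndarray,
        subject_ids: list[str],
        variant_ids: list[str],
    ) -> None:
        dosages = np.asarray(dosages, dtype=float)
        if dosages.shape != (len(subject_ids), len(variant_ids)):
            raise ValueError(
                f"dosage matrix shape {dosages.shape} does not match "
                f"{len(subject_ids)} subjects x {len(variant_ids)} variants"
            )
        observed = dosages[~np.isnan(dosages)]
        if observed.size and not np.isin(observed, (0.0, 1.0, 2.0)).all():
            raise ValueError("raw dosages must be 0, 1, 2 or NaN")
        self.dosages = dosages
        self.subject_ids = list(subject_ids)
        self.variant_ids = list(variant_ids)

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    def column(self, variant_id: str) -> np.ndarray:
        return self.dosages[:, self.variant_ids.index(variant_id)]

    def subset(self, variant_ids: list[str]) -> "GenotypeMatrix":
        idx = [self.variant_ids.index(v) for v in variant_ids]
        return GenotypeMatrix(self.dosages[:, idx], self.subject_ids, list(variant_ids))

    def tally(self, variant_id: str, case_mask: np.ndarray) -> tuple[GroupCounts, GroupCounts]:
        """Per-group genotype counts for one column; must match the records."""
        col = self.column(variant_id)
        out = []
        for mask in (case_mask, ~case_mask):
            g = col[mask]
            out.append(
                GroupCounts(
                    hom_ref=int(np.sum(g == 0)),
                    het=int(np.sum(g == 1)),
                    hom_alt=int(np.sum(g == 2)),
                    missing=int(np.sum(np.isnan(g))),
                )
            )
        return out[0], out[1]


def filter_variants(
    variants: list[VariantRecord],
    maf_cutoff: float = MAF_CUTOFF,
    max_missing: float = MAX_MISSING_FRACTION,
) -> tuple[list[VariantRecord], list[tuple[VariantRecord, str]]]:
    """Split variants into kept and (variant, reason) excluded.

    Reasons, checked in order: ``"missingness"``, ``"het_deficit"``, ``"maf"``.
    The het-deficit and missingness rules are evaluated on the pooled
    cases+controls tallies; rarity is per group (rare in either suffices).
    """
    kept: list[VariantRecord] = []
    excluded: list[tuple[VariantRecord, str]] = []
    for v in variants:
        het = v.cases.het + v.controls.het
        hom_ref = v.cases.hom_ref + v.controls.hom_ref
        hom_alt = v.cases.hom_alt + v.controls.hom_alt
        if v.missing_fraction > max_missing:
            excluded.append((v, "missingness"))
        elif het < hom_ref and het < hom_alt:
            excluded.append((v, "het_deficit"))
        elif not (v.maf_cases <= maf_cutoff or v.maf_controls <= maf_cutoff):
            excluded.append((v, "maf"))
        else:
            kept.append(v)
    return kept, excluded


def impute_missing(column: np.ndarray) -> np.ndarray:
    """Replace NaN entries by the mean observed dosage (pooled subjects)."""
    column = np.asarray(column, dtype=float)
    observed = ~np.isnan(column)
    if not observed.any():
        raise ValueError(
            "all genotypes missing; such variants should have been removed "
            "by the missingness filter"
        )
    out = column.copy()
    out[~observed] = column[observed].mean()
    return out


def gene_burden_scores(
    genotypes: GenotypeMatrix,
    variants: list[VariantRecord],
    scheme: WeightScheme | None = None,
) -> np.ndarray:
    """Per-subject weighted burden score over the kept variants of one gene.

    score_s = sum_v combined_weight(v) * dosage(s, v), with missing dosages
    imputed to the per-variant observed mean. Flipped records read the
    matching column as 2 - dosage so the minor allele is counted.
    """
    scheme = scheme or WeightScheme()
    ids = [v.variant_id for v in variants]
    if set(ids) - set(genotypes.variant_ids):
        raise ValueError("variant list contains ids absent from the genotype matrix")
    scores = np.zeros(genotypes.n_subjects)
    for v in variants:
        col = genotypes.column(v.variant_id)
        if v.flipped:
            col = 2.0 - col
        dosage = impute_missing(col) if np.isnan(col).any() else col
        maf = min(v.maf_overall, scheme.maf_cap)  # guard: kept via per-group rule
        scores += combined_weight(maf, v.annotation, scheme) * dosage
    return scores
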