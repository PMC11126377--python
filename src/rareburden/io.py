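"""File formats and the end-to-end pipeline.

Inputs
------
* genotypes: VCF (plain or bgzipped) with GT; multiallelic sites are
  decomposed into one biallelic record per alternate allele;
* annotations: TSV with columns ``variant_id  gene  category  polyphen  sift``
  (variant keys ``chrom:pos:ref:alt``, 1-based positions, verbatim from the
  VCF);
* phenotypes: TSV with columns ``subject_id  phenotype  sex  pc1..pc20``,
  phenotype coded 1 = case / 0 = control.

Subjects present in both the VCF and the phenotype table are intersected (in
VCF sample order, which every later stage preserves); variants without an
annotation row are dropped. Both events are logged and counted in the run
summary JSON.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .association import (
    N_PCS,
    CohortTable,
    ConvergenceError,
    GeneResult,
    fit_burden_lrt,
    fit_null_model,
)
from .categories import (
    CATEGORY_LABELS,
    count_categories,
    fit_category_regression,
)
from .filtering import (
    GenotypeMatrix,
    VariantRecord,
    filter_variants,
    gene_burden_scores,
)
from .simulate import SimulatedCohort
from .weights import (
    CATEGORIES,
    VariantAnnotation,
    WeightScheme,
    read_weight_scheme,
)

logger = logging.getLogger("rareburden")

__all__ = [
    "RunConfig",
    "read_vcf",
    "read_annotation_table",
    "read_phenotype_table",
    "read_inputs",
    "run_pipeline",
    "run_category_pipeline",
    "write_vcf",
    "write_annotation_table",
    "write_phenotype_table",
    "write_cohort_files",
    "write_gene_results",
    "write_category_results",
]


@dataclass
class RunConfig:
    """Paths and options for one pipeline run; paths are checked up front."""

    vcf: Path
    annotation: Path
    phenotype: Path
    out_dir: Path
    weights: Path | None = None
    n_tests: int = 47
    alpha: float = 0.05
    gene: str | None = None  # restrict to one gene (category analysis)
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("vcf", "annotation", "phenotype", "out_dir", "weights"):
            value = getattr(self, name)
            if value is not None:
                setattr(self, name, Path(value))
        for name in ("vcf", "annotation", "phenotype"):
            if not getattr(self, name).exists():
                raise FileNotFoundError(f"{name} file not found: {getattr(self, name)}")
        if self.weights is not None and not self.weights.exists():
            raise FileNotFoundError(f"weights file not found: {self.weights}")

    def scheme(self) -> WeightScheme:
        return read_weight_scheme(self.weights) if self.weights else WeightScheme()


# -- readers -----------------------------------------------------------------


def read_vcf(path: str | Path) -> tuple[np.ndarray, list[str], list[str]]:
    """Read GT dosages; returns (dosage matrix, subject ids, variant ids).

    Multiallelic sites are decomposed: alternate allele k becomes its own
    biallelic record with per-sample dosage = number of k alleles. A genotype
    with any missing allele is missing (NaN) in every decomposed record.
    """
    vcf = VCF(str(path))
    subjects = list(vcf.samples)
    if len(set(subjects)) != len(subjects):
        raise ValueError(f"duplicate sample ids in {path}")
    columns: list[np.ndarray] = []
    ids: list[str] = []
    for variant in vcf:
        alleles = np.array(variant.genotypes, dtype=int)[:, :2]
        missing = (alleles < 0).any(axis=1)
        for k, alt in enumerate(variant.ALT, start=1):
            dosage = (alleles == k).sum(axis=1).astype(float)
            dosage[missing] = np.nan
            columns.append(dosage)
            ids.append(f"{variant.CHROM}:{variant.POS}:{variant.REF}:{alt}")
    matrix = (
        np.column_stack(columns) if columns else np.empty((len(subjects), 0))
    )
    return matrix, subjects, ids


def read_annotation_table(path: str | Path) -> pd.DataFrame:
    """TSV of variant_id, gene, category, polyphen, sift (indexed by variant)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("none")
    required = {"variant_id", "gene", "category", "polyphen", "sift"}
    if missing := required - set(df.columns):
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    if df["variant_id"].duplicated().any():
        raise ValueError("duplicate variant ids in annotation table")
    bad = set(df["category"]) - set(CATEGORIES)
    if bad:
        raise ValueError(f"unknown functional categories in annotation table: {sorted(bad)}")
    return df.set_index("variant_id")


def read_phenotype_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        raise ValueError(f"phenotype table {path} is empty")
    required = ["subject_id", "phenotype", "sex"] + [f"pc{i}" for i in range(1, N_PCS + 1)]
    if missing := set(required) - set(df.columns):
        raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
    if df["subject_id"].duplicated().any():
        raise ValueError("duplicate subject ids in phenotype table")
    if not df["phenotype"].isin((0, 1)).all():
        raise ValueError("phenotype must be coded 0 (control) / 1 (case)")
    return df.set_index("subject_id")


def read_inputs(
    config: RunConfig,
) -> tuple[GenotypeMatrix, list[VariantRecord], CohortTable]:
    """Load and join the three input files into aligned in-memory structures."""
    dosages, vcf_subjects, variant_ids = read_vcf(config.vcf)
    anno = read_annotation_table(config.annotation)
    pheno = read_phenotype_table(config.phenotype)

    overlap = [s for s in vcf_subjects if s in pheno.index]
    if not overlap:
        raise ValueError("no subjects shared between VCF and phenotype table")
    dropped = (len(vcf_subjects) - len(overlap)) + (len(pheno) - len(overlap))
    if dropped:
        logger.info("subject intersection: %d subjects used, %d dropped", len(overlap), dropped)
    rows = [vcf_subjects.index(s) for s in overlap]
    pheno = pheno.loc[overlap]

    annotated = [i for i, v in enumerate(variant_ids) if v in anno.index]
    n_unannotated = len(variant_ids) - len(annotated)
    if n_unannotated:
        logger.info("dropped %d variants without annotation", n_unannotated)
    kept_ids = [variant_ids[i] for i in annotated]
    genotypes = GenotypeMatrix(dosages[np.ix_(rows, annotated)], overlap, kept_ids)

    cohort = CohortTable(
        overlap,
        pheno["phenotype"].to_numpy(),
        pheno[["sex"] + [f"pc{i}" for i in range(1, N_PCS + 1)]].to_numpy(float),
    )
    case = cohort.case_mask
    records = []
    for vid in kept_ids:
        row = anno.loc[vid]
        ann = VariantAnnotation(row["category"], row["polyphen"], row["sift"])
        records.append(
            VariantRecord.from_counts(
                vid, row["gene"], *genotypes.tally(vid, case), annotation=ann
            )
        )
    return genotypes, records, cohort


# -- writers -----------------------------------------------------------------

_GT_STRING = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf(genotypes: GenotypeMatrix, path: str | Path) -> None:
    """Write raw dosages as a minimal single-sample-per-column VCF."""
    contigs = sorted({v.split(":")[0] for v in genotypes.variant_ids})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.subject_ids)
            + "\n"
        )
        for j, vid in enumerate(genotypes.variant_ids):
            chrom, pos, ref, alt = vid.split(":")
            col = genotypes.dosages[:, j]
            gts = "\t".join(
                "./." if np.isnan(g) else _GT_STRING[g] for g in col
            )
            fh.write(f"{chrom}\t{pos}\t{vid}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gts}\n")


def write_annotation_table(variants: list[VariantRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "variant_id": [v.variant_id for v in variants],
            "gene": [v.gene for v in variants],
            "category": [v.annotation.category for v in variants],
            "polyphen": [v.annotation.polyphen for v in variants],
            "sift": [v.annotation.sift for v in variants],
        }
    ).to_csv(path, sep="\t", index=False)


def write_phenotype_table(cohort: CohortTable, path: str | Path) -> None:
    cohort.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_cohort_files(
    sim: SimulatedCohort, out_dir: str | Path, prefix: str = "cohort"
) -> dict[str, Path]:
    """Dump a simulated cohort as the VCF + TSV trio the pipeline reads."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / f"{prefix}.vcf",
        "annotation": out / f"{prefix}.anno.tsv",
        "phenotype": out / f"{prefix}.pheno.tsv",
    }
    write_vcf(sim.genotypes, paths["vcf"])
    write_annotation_table(sim.variants, paths["annotation"])
    write_phenotype_table(sim.cohort, paths["phenotype"])
    return paths


def write_gene_results(results: list[GeneResult], path: str | Path) -> None:
    """Gene results TSV, one row per gene, sorted by |SLP| descending."""
    df = pd.DataFrame(
        {
            "gene": [r.gene for r in results],
            "n_variants": [r.n_variants_kept for r in results],
            "lrt_chisq": [round(r.lrt_chisq, 6) for r in results],
            "p": [f"{r.p_value:.6g}" for r in results],
            "SLP": [round(r.slp, 4) for r in results],
        }
    )
    df = df.iloc[df["SLP"].abs().sort_values(ascending=False, kind="stable").index]
    df.to_csv(path, sep="\t", index=False)


def write_category_results(results, path: str | Path) -> None:
    rows = []
    for r in results:
        blank = not np.isfinite(r.or_estimate)
        rows.append(
            {
                "category": CATEGORY_LABELS[r.category],
                "n_variants": r.n_variants,
                "total_controls": round(r.total_count_controls, 4),
                "mean_controls": round(r.mean_count_controls, 6),
                "total_cases": round(r.total_count_cases, 4),
                "mean_cases": round(r.mean_count_cases, 6),
                "OR_95CI": ""
                if blank
                else f"{r.or_estimate:.2f} ({r.ci_low:.2f}-{r.ci_high:.2f})",
                "SLP": "" if blank else round(r.wald_slp, 4),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_excluded_report(
    excluded: list[tuple[VariantRecord, str]], path: str | Path
) -> None:
    pd.DataFrame(
        {
            "variant_id": [v.variant_id for v, _ in excluded],
            "reason": [r for _, r in excluded],
        }
    ).to_csv(path, sep="\t", index=False)


# -- pipelines ---------------------------------------------------------------


def run_pipeline(config: RunConfig) -> list[GeneResult]:
    """filter -> impute -> score -> LRT for every gene; write result files.

    A per-gene fit failure is recorded in the results file (NaN row) and does
    not abort the other genes. Outputs: ``gene_results.tsv``,
    ``excluded_variants.tsv`` and ``run_summary.json`` in ``out_dir``.
    """
    scheme = config.scheme()
    genotypes, records, cohort = read_inputs(config)
    kept, excluded = filter_variants(records)
    genes = sorted({v.gene for v in records})
    null_res = fit_null_model(cohort)

    results: list[GeneResult] = []
    failures: dict[str, str] = {}
    for gene in genes:
        gene_kept = [v for v in kept if v.gene == gene]
        if not gene_kept:
            results.append(GeneResult(gene, 0, 0.0, 1.0, 0.0, "null"))
            continue
        scores = gene_burden_scores(genotypes, gene_kept, scheme)
        try:
            results.append(
                fit_burden_lrt(
                    scores, cohort, gene=gene, n_variants_kept=len(gene_kept),
                    null_result=null_res,
                )
            )
        except ConvergenceError as exc:
            failures[gene] = str(exc)
            results.append(
                GeneResult(gene, len(gene_kept), float("nan"), float("nan"),
                           float("nan"), "null")
            )

    config.out_dir.mkdir(parents=True, exist_ok=True)
    write_gene_results(results, config.out_dir / "gene_results.tsv")
    write_excluded_report(excluded, config.out_dir / "excluded_variants.tsv")
    reasons = sorted(r for _, r in excluded)
    summary = {
        "n_subjects": cohort.n_subjects,
        "n_cases": int(cohort.phenotype.sum()),
        "n_variants_input": len(records),
        "n_variants_kept": len(kept),
        "n_excluded_by_reason": {r: reasons.count(r) for r in set(reasons)},
        "n_genes": len(genes),
        "slp_threshold": round(
            -np.log10(config.alpha / config.n_tests), 2
        ),
        "fit_failures": failures,
    }
    (config.out_dir / "run_summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )
    return results


def run_category_pipeline(config: RunConfig):
    """Category decomposition for one gene; writes ``category_results.tsv``."""
    if not config.gene:
        raise ValueError("category analysis requires a gene symbol")
    genotypes, records, cohort = read_inputs(config)
    gene_records = [v for v in records if v.gene == config.gene]
    if not gene_records:
        raise ValueError(f"no variants annotated to gene {config.gene!r}")
    kept, _ = filter_variants(gene_records)
    if not kept:
        raise ValueError(f"no variants of gene {config.gene!r} pass the filters")
    counts = count_categories(genotypes, kept)
    results = fit_category_regression(counts, cohort, kept)
    config.out_dir.mkdir(parents=True, exist_ok=True)
    write_category_results(results, config.out_dir / "category_results.tsv")
    return results
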