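"""Gene-wise association: logistic-regression likelihood ratio test and SLPs.

For each gene, two logistic models of case status are compared by maximum
likelihood:

    reduced:  logit P(case) ~ sex + pc1..pc20
    full:     logit P(case) ~ sex + pc1..pc20 + burden_score

The LRT statistic 2*(ll_full - ll_reduced) is referred to chi-square with
1 df. Significance is summarised as a signed log p-value (SLP): magnitude
-log10(p), positive when the burden score is higher in cases (positive
fitted coefficient), negative when higher in controls. |SLP| = 3 means
p = 0.001.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "CohortTable",
    "GeneResult",
    "ConvergenceError",
    "fit_null_model",
    "fit_burden_lrt",
    "slp_from_p",
    "significance_threshold",
]

N_PCS = 20

_MAXITER = 100
_TOL = 1e-8


class ConvergenceError(RuntimeError):
    """Logistic fit failed to converge (including separated data)."""


@dataclass
class CohortTable:
    """Subjects with case/control status, sex and 20 ancestry PCs.

    ``covariates`` is the n x 21 design block [sex, pc1..pc20]; an intercept
    is added at fit time.
    """

    subject_ids: list[str]
    phenotype: np.ndarray  # 1 = case, 0 = control
    covariates: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.phenotype = np.asarray(self.phenotype, dtype=int)
        self.covariates = np.asarray(self.covariates, dtype=float)
        n = len(self.subject_ids)
        if self.phenotype.shape != (n,):
            raise ValueError("phenotype length does not match subject ids")
        if self.covariates.shape != (n, 1 + N_PCS):
            raise ValueError(f"covariates must be n x {1 + N_PCS} [sex, pc1..pc{N_PCS}]")
        if not np.isin(self.phenotype, (0, 1)).all():
            raise ValueError("phenotype must be coded 0 (control) / 1 (case)")
        if np.isnan(self.covariates).any():
            raise ValueError("covariates contain missing values")
        if self.phenotype.min() == self.phenotype.max():
            raise ValueError("cohort needs at least one case and one control")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def case_mask(self) -> np.ndarray:
        return self.phenotype == 1

    @property
    def covariate_names(self) -> list[str]:
        return ["sex"] + [f"pc{i}" for i in range(1, N_PCS + 1)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.covariates, columns=self.covariate_names)
        df.insert(0, "phenotype", self.phenotype)
        df.insert(0, "subject_id", self.subject_ids)
        return df


@dataclass(frozen=True)
class GeneResult:
    gene: str
    n_variants_kept: int
    lrt_chisq: float
    p_value: float
    slp: float
    direction: str  # cases_higher | controls_higher | null
    coefficient: float = float("nan")


def _fit_logit(y: np.ndarray, X: np.ndarray, label: str) -> sm.discrete.discrete_model.BinaryResults:
    from statsmodels.tools.sm_exceptions import (
        ConvergenceWarning,
        PerfectSeparationWarning,
    )

    model = sm.Logit(y, X)
    with warnings.catch_warnings():
        # separation and non-convergence are fatal; transient overflow in the
        # Newton iterations is not
        warnings.simplefilter("error", PerfectSeparationWarning)
        warnings.simplefilter("error", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        try:
            res = model.fit(method="newton", maxiter=_MAXITER, tol=_TOL, disp=0)
        except Exception as exc:  # separation, singular Hessian, no convergence
            raise ConvergenceError(f"logistic fit failed for {label}: {exc}") from exc
    if not res.mle_retvals.get("converged", False):
        raise ConvergenceError(f"logistic fit did not converge for {label}")
    if not np.isfinite(res.params).all() or not np.isfinite(res.llf):
        raise ConvergenceError(f"logistic fit diverged for {label}")
    return res


def fit_null_model(cohort: CohortTable) -> sm.discrete.discrete_model.BinaryResults:
    """Covariates-only logistic fit, reusable across the genes of one cohort."""
    X = sm.add_constant(cohort.covariates, has_constant="add")
    return _fit_logit(cohort.phenotype, X, "covariates-only model")


def fit_burden_lrt(
    scores: np.ndarray,
    cohort: CohortTable,
    gene: str = "gene",
    n_variants_kept: int = 0,
    null_result=None,
) -> GeneResult:
    """LRT of the gene-wise burden score on top of sex + 20 PCs.

    A zero-variance score carries no information and yields the defined
    degenerate result p = 1, SLP = 0, direction "null". Pass ``null_result``
    (from :func:`fit_null_model`) to avoid refitting the reduced model per
    gene.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.shape != (cohort.n_subjects,):
        raise ValueError("scores are not aligned with the cohort rows")
    if np.ptp(scores) == 0:
        return GeneResult(gene, n_variants_kept, 0.0, 1.0, 0.0, "null")

    if null_result is None:
        null_result = fit_null_model(cohort)
    X_full = sm.add_constant(
        np.column_stack([cohort.covariates, scores]), has_constant="add"
    )
    full = _fit_logit(cohort.phenotype, X_full, f"gene {gene}")
    chisq = max(0.0, 2.0 * (full.llf - null_result.llf))
    p = float(stats.chi2.sf(chisq, df=1))
    coef = float(full.params[-1])
    if p >= 1.0 or coef == 0.0:
        direction = "null"
    elif coef > 0:
        direction = "cases_higher"
    else:
        direction = "controls_higher"
    return GeneResult(
        gene=gene,
        n_variants_kept=n_variants_kept,
        lrt_chisq=float(chisq),
        p_value=min(p, 1.0),
        slp=slp_from_p(min(p, 1.0), direction),
        direction=direction,
        coefficient=coef,
    )


def slp_from_p(p: float, direction: str) -> float:
    """Signed log10 p: +|log10 p| when cases score higher, - when controls do."""
    if not 0 < p <= 1:
        raise ValueError(f"p-value must be in (0, 1], got {p}")
    if direction not in ("cases_higher", "controls_higher", "null"):
        raise ValueError(f"unknown direction {direction!r}")
    if p == 1.0 or direction == "null":
        return 0.0
    magnitude = float(-np.log10(p))
    return magnitude if direction == "cases_higher" else -magnitude


def significance_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """Bonferroni SLP-magnitude threshold: -log10(alpha / n_tests).

    47 gene tests at alpha 0.05 give 2.97; an exome-wide 22,642 gene scan
    gives 5.66 (both to two decimals).
    """
    if n_tests < 1 or int(n_tests) != n_tests:
        raise ValueError(f"n_tests must be a positive integer, got {n_tests}")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    return float(-np.log10(alpha / n_tests))
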