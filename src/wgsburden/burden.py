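"""MAF-weighted burden computation and the covariate-adjusted logistic
burden test.

The central statistic of the package: for a set of variants, each
individual's burden is the sum of alt-allele dosages weighted by the
Beta(1, 25) density evaluated at the variant's minor allele frequency
(the SKAT/WGScan convention, which strongly upweights rarer variants).
Case/control or study/study status is then regressed on that burden with
logistic regression, adjusting for covariates; the Wald test on the
burden coefficient is the reported test.  Genomic inflation of a scan is
summarised with the genomic-control lambda.
"""

from __future__ import annotations

import dataclasses
import warnings
from fractions import Fraction
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .firth import firth_logistic

__all__ = [
    "WeightScheme",
    "BurdenDesign",
    "variant_weight",
    "sample_burden",
    "total_burden_covariate",
    "BurdenAssociation",
    "BurdenAssociationResults",
    "burden_logistic_test",
    "lambda_gc",
    "bonferroni_threshold",
    "run_category_scan",
    "CategoryScanResult",
]

#: median of the 1-df chi-square distribution
CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, 1))


@dataclasses.dataclass(frozen=True)
class WeightScheme:
    """Beta-density variant weights, ``weight(m) = Beta(m; a, b)``.

    With the defaults (a=1, b=25) the weight is ``25 (1-m)^24``: ~25 for
    singletons, decaying steeply with frequency.
    """

    a: float = 1.0
    b: float = 25.0

    def __call__(self, maf):
        return variant_weight(maf, self)


def variant_weight(maf, scheme: WeightScheme = WeightScheme()):
    """Beta-density weight at minor allele frequency ``maf`` (in (0, 1))."""
    m = np.asarray(maf, dtype=np.float64)
    if np.any((m <= 0) | (m >= 1)):
        raise ValueError("MAF must lie strictly inside (0, 1)")
    out = stats.beta.pdf(m, scheme.a, scheme.b)
    return float(out) if np.isscalar(maf) else out


@dataclasses.dataclass
class BurdenDesign:
    """Variant-filtering and covariate choices for burden tests."""

    maf_max: float = 0.05
    snv_only: bool = True
    exclude_excluded_regions: bool = True
    covariates: Sequence[str] = dataclasses.field(
        default_factory=lambda: [f"pc{i}" for i in range(1, 11)] + ["sex"]
    )
    include_total_burden: bool = True
    metadata_pc_columns: Sequence[str] = dataclasses.field(default_factory=list)
    weights: WeightScheme = dataclasses.field(default_factory=WeightScheme)

    def __post_init__(self):
        if not (0 < self.maf_max <= 0.5):
            raise ValueError("maf_max must lie in (0, 0.5]")

    def covariate_columns(self, with_metadata_pcs: bool = False):
        cols = list(self.covariates)
        if with_metadata_pcs:
            cols += list(self.metadata_pc_columns)
        return cols


def analysis_mask(
    maf: np.ndarray,
    is_snv: np.ndarray,
    excluded: Optional[np.ndarray],
    design: BurdenDesign,
) -> np.ndarray:
    """Boolean mask of variants entering the analysis set."""
    mask = (maf > 0) & (maf < design.maf_max)
    if design.snv_only:
        mask &= np.asarray(is_snv, dtype=bool)
    if design.exclude_excluded_regions and excluded is not None:
        mask &= ~np.asarray(excluded, dtype=bool)
    return mask


def sample_burden(
    dosage: np.ndarray,
    weights: np.ndarray,
    member_idx: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Per-sample weighted burden over a variant set.

    ``burden_i = sum_v weight_v * dosage_iv`` over the member variants.
    An empty member set yields all-zero burdens.
    """
    if member_idx is not None:
        member_idx = np.asarray(member_idx)
        if member_idx.size and (
            member_idx.min() < 0 or member_idx.max() >= dosage.shape[1]
        ):
            bad = member_idx[(member_idx < 0) | (member_idx >= dosage.shape[1])]
            raise IndexError(f"variant indices out of range: {bad[:5].tolist()}")
        if member_idx.size == 0:
            return np.zeros(dosage.shape[0])
        return dosage[:, member_idx] @ weights[member_idx]
    return dosage @ weights


def total_burden_covariate(dosage: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Weighted total burden over the whole analysis set (the per-sample
    variant-load covariate)."""
    return sample_burden(dosage, weights, None)


# ---------------------------------------------------------------------------
# the logistic burden test, statsmodels-style
# ---------------------------------------------------------------------------


class BurdenAssociation:
    """Logistic regression of a binary outcome on a per-sample burden.

    Parameters
    ----------
    endog : (n,) 0/1 outcome (1 = first-listed group, e.g. cases).
    burden : (n,) per-sample weighted burden (the predictor of interest).
    exog : (n, k) additional covariates, without an intercept column.
    exog_names : names for the covariate columns (diagnostics only).
    """

    def __init__(self, endog, burden, exog=None, exog_names=None):
        self.endog = np.asarray(endog, dtype=np.float64)
        self.burden = np.asarray(burden, dtype=np.float64)
        n = self.endog.shape[0]
        if self.burden.shape[0] != n:
            raise ValueError("endog and burden lengths differ")
        if exog is None:
            exog = np.empty((n, 0))
        self.exog = np.asarray(exog, dtype=np.float64)
        if np.isnan(self.endog).any() or np.isnan(self.burden).any() or np.isnan(self.exog).any():
            raise ValueError("missing values in test inputs")
        classes = np.unique(self.endog)
        if not np.all(np.isin(classes, [0.0, 1.0])) or classes.size < 2:
            raise ValueError("outcome must contain both 0 and 1")
        k = self.exog.shape[1]
        self.exog_names = (
            list(exog_names)
            if exog_names is not None
            else [f"x{i+1}" for i in range(k)]
        )

    def _design(self):
        n = self.endog.shape[0]
        return np.column_stack([np.ones(n), self.burden, self.exog])

    def _check_rank(self, X):
        from scipy import linalg

        names = ["const", "burden"] + self.exog_names
        # pivoted QR flags (nearly) collinear columns
        _, rmat, piv = linalg.qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(rmat))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps * 1e3
        bad = [names[piv[j]] for j in np.where(diag < tol)[0]]
        if bad:
            raise ValueError(f"rank-deficient design; collinear columns: {bad}")

    def fit(
        self,
        method: str = "wald",
        maxiter: int = 50,
        beta_max: float = 15.0,
    ) -> "BurdenAssociationResults":
        """Maximum-likelihood fit with automatic Firth fallback.

        The fallback triggers on non-convergence within ``maxiter``
        Newton iterations or a burden coefficient exceeding ``beta_max``
        in absolute value — both symptoms of separation.
        """
        import statsmodels.api as sm

        if np.ptp(self.burden) == 0.0:
            return BurdenAssociationResults(
                model=self,
                beta=0.0,
                se=np.inf,
                pvalue=1.0,
                converged=False,
                method_used="degenerate",
                degenerate=True,
            )
        X = self._design()
        self._check_rank(X)
        use_firth = False
        beta = se = None
        llf = llnull = None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = sm.Logit(self.endog, X).fit(disp=0, maxiter=maxiter)
                converged = bool(res.mle_retvals.get("converged", False))
                beta = res.params[1]
                se = res.bse[1]
                llf = float(res.llf)
                if (
                    not converged
                    or not np.isfinite(se)
                    or abs(beta) > beta_max
                ):
                    use_firth = True
            except Exception:
                use_firth = True
        if use_firth:
            params, bse, converged = firth_logistic(self.endog, X)
            beta, se = params[1], bse[1]
            method_used = "firth"
        else:
            method_used = "mle"
        if method == "lrt" and method_used == "mle":
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                Xnull = np.delete(X, 1, axis=1)
                resnull = sm.Logit(self.endog, Xnull).fit(disp=0, maxiter=maxiter)
                llnull = float(resnull.llf)
            lr = max(0.0, 2.0 * (llf - llnull))
            pvalue = float(stats.chi2.sf(lr, 1))
        else:
            z = beta / se if se > 0 and np.isfinite(se) else 0.0
            pvalue = float(2.0 * stats.norm.sf(abs(z)))
        return BurdenAssociationResults(
            model=self,
            beta=float(beta),
            se=float(se),
            pvalue=min(max(pvalue, np.nextafter(0, 1)), 1.0),
            converged=bool(converged),
            method_used=method_used,
        )


@dataclasses.dataclass
class BurdenAssociationResults:
    """Fitted burden-test results: effect, uncertainty, p-value."""

    model: BurdenAssociation
    beta: float
    se: float
    pvalue: float
    converged: bool
    method_used: str
    degenerate: bool = False
    label: Optional[str] = None
    n_variants: Optional[int] = None

    @property
    def or_(self) -> float:
        return float(np.exp(self.beta))

    @property
    def zvalue(self) -> float:
        return self.beta / self.se if self.se > 0 and np.isfinite(self.se) else 0.0

    def mean_burden_by_group(self):
        y = self.model.endog
        b = self.model.burden
        return {1: float(b[y == 1].mean()), 0: float(b[y == 0].mean())}

    def signed_log10p(self) -> float:
        """-log10 p signed by enrichment direction (positive = first group)."""
        return float(np.sign(self.beta) * -np.log10(self.pvalue))

    def summary(self) -> str:
        by = self.mean_burden_by_group()
        lines = [
            "Weighted burden logistic association",
            "====================================",
            f"label:            {self.label or '-'}",
            f"n samples:        {self.model.endog.shape[0]:d}"
            f"  (group1 {int(self.model.endog.sum())}, "
            f"group0 {int((1 - self.model.endog).sum())})",
            f"n variants:       {self.n_variants if self.n_variants is not None else '-'}",
            f"method:           {self.method_used}",
            f"beta (log-OR):    {self.beta:+.4f}  (se {self.se:.4f})",
            f"OR per unit:      {self.or_:.4f}",
            f"p (two-sided):    {self.pvalue:.3e}",
            f"mean burden:      group1 {by[1]:.3f} / group0 {by[0]:.3f}",
            f"converged:        {self.converged}",
        ]
        return "\n".join(lines)


def burden_logistic_test(
    outcome, burden, covariates=None, covariate_names=None, **fit_kwargs
) -> BurdenAssociationResults:
    """Functional wrapper: build and fit a :class:`BurdenAssociation`."""
    return BurdenAssociation(
        outcome, burden, covariates, exog_names=covariate_names
    ).fit(**fit_kwargs)


# ---------------------------------------------------------------------------
# scan-level summaries
# ---------------------------------------------------------------------------


def lambda_gc(pvalues) -> float:
    """Genomic-control lambda: median chi2(1) quantile of the p-values
    divided by the chi2(1) median (0.4549...)."""
    p = np.asarray(pvalues, dtype=np.float64)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    chi2 = stats.chi2.isf(p, 1)
    return float(np.median(chi2) / CHI2_1_MEDIAN)


def bonferroni_threshold(alpha, n_tests: int, n_analyses: int = 1) -> float:
    """Family-wise threshold alpha / (n_tests * n_analyses), computed as an
    exact rational before float conversion."""
    frac = Fraction(str(alpha)) / (Fraction(n_tests) * Fraction(n_analyses))
    return float(frac)


@dataclasses.dataclass
class CategoryScanResult:
    """Per-category burden tests plus inflation summary."""

    results: pd.DataFrame
    lambda_gc: float
    threshold_single: float
    threshold_all_comparisons: float

    def min_p_category(self) -> str:
        return str(self.results.loc[self.results["p"].idxmin(), "category"])


def run_category_scan(
    variants,
    annotation,
    samples,
    comparison,
    design: BurdenDesign,
    systems=("chrom_state", "cons_state"),
    with_metadata_pcs: bool = False,
    n_comparisons: int = 7,
    family_alpha: float = 0.05,
) -> CategoryScanResult:
    """Burden-test every annotation category of the given systems.

    Parameters
    ----------
    variants : VariantTable
    annotation : VariantAnnotationSet from :func:`annotate_variants`
    samples : SampleFrame
    comparison : pair of group selector names (first = "case" direction)
    design : BurdenDesign
    systems : annotation systems to scan (each label is one test)
    """
    sel1, sel2 = comparison
    m1 = samples.group_mask(sel1)
    m2 = samples.group_mask(sel2)
    if np.any(m1 & m2):
        raise ValueError(f"comparison groups {sel1!r}/{sel2!r} overlap")
    sub = m1 | m2
    y = m1[sub].astype(np.float64)

    idx = variants.sample_index(samples.sample_ids[sub])
    maf = variants.maf(idx)
    mask = analysis_mask(
        maf, variants.variants["is_snv"].to_numpy(), annotation.excluded, design
    )
    weights = np.zeros(variants.n_variants)
    weights[mask] = variant_weight(maf[mask], design.weights)
    dosage = variants.dosage(idx)

    cov_cols = design.covariate_columns(with_metadata_pcs)
    cov_names: list = []
    cov = samples.covariate_matrix(cov_cols, mask=sub, names_out=cov_names)
    if design.include_total_burden:
        total = total_burden_covariate(dosage, weights)
        cov = np.column_stack([cov, total])
        cov_names = cov_names + ["total_burden"]

    n_tests = sum(len(annotation.label_universe[s]) for s in systems)
    thr_single = bonferroni_threshold(family_alpha, n_tests)
    thr_all = bonferroni_threshold(family_alpha, n_tests, n_comparisons)

    rows = []
    for system in systems:
        for label in annotation.label_universe[system]:
            members = annotation.members(system, label)
            members = members[mask[members]]
            if members.size == 0:
                warnings.warn(
                    f"category {system}:{label} has no analysis-set variants; skipped"
                )
                continue
            b = sample_burden(dosage, weights, members)
            res = burden_logistic_test(y, b, cov, covariate_names=cov_names)
            rows.append(
                {
                    "category": label,
                    "system": system,
                    "n_variants": int(members.size),
                    "beta": res.beta,
                    "se": res.se,
                    "or": res.or_,
                    "p": res.pvalue,
                    "direction": int(np.sign(res.beta)) or 0,
                    "signed_log10p": res.signed_log10p(),
                    "method_used": res.method_used,
                    "converged": res.converged,
                    "significant_single": res.pvalue < thr_single,
                    "significant_all_comparisons": res.pvalue < thr_all,
                }
            )
    df = pd.DataFrame(rows)
    lam = lambda_gc(df["p"].to_numpy()) if len(df) else float("nan")
    return CategoryScanResult(
        results=df,
        lambda_gc=lam,
        threshold_single=thr_single,
        threshold_all_comparisons=thr_all,
    )
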