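"""Single-variant association testing.

A covariate-adjusted logistic score test per qualifying variant
(MAC > 20 in the tested individuals by default), with score-based OR and
CI reporting, Firth refits where separation makes the one-step estimate
unreliable, and a Fisher's-exact fallback for very rare alleles.  The
reference-genome allele is the OR reference.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .burden import lambda_gc
from .firth import firth_logistic
from .score import LogisticScoreEngine

__all__ = [
    "GwasThresholds",
    "single_variant_scan",
    "SingleVariantScanResult",
    "fisher_exact_allelic",
]

logger = logging.getLogger(__name__)

GENOME_WIDE_ALPHA = 5e-9


@dataclasses.dataclass(frozen=True)
class GwasThresholds:
    """Genome-wide and multiple-comparison-conservative thresholds."""

    genome_wide: float = GENOME_WIDE_ALPHA
    n_comparisons: int = 7

    @property
    def conservative(self) -> float:
        return self.genome_wide / self.n_comparisons


def fisher_exact_allelic(mac_case: int, n_case: int, mac_ctrl: int, n_ctrl: int):
    """Two-sided Fisher's exact test on the 2x2 allele-count table.

    Rows are alt/ref allele counts (2n alleles per group); the OR is the
    cross-product ratio with a Haldane-Anscombe 0.5 correction when any
    cell is zero.  Two-sidedness follows the minimum-likelihood rule.
    """
    for v in (mac_case, n_case, mac_ctrl, n_ctrl):
        if v < 0:
            raise ValueError("counts must be non-negative")
    if mac_case > 2 * n_case or mac_ctrl > 2 * n_ctrl:
        raise ValueError("allele count exceeds 2n of its group")
    table = np.array(
        [[mac_case, 2 * n_case - mac_case], [mac_ctrl, 2 * n_ctrl - mac_ctrl]]
    )
    _, p = stats.fisher_exact(table, alternative="two-sided")
    a, b, c, d = table.ravel().astype(float)
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a * d) / (b * c)
    return float(or_), float(p)


@dataclasses.dataclass
class SingleVariantScanResult:
    """Per-variant association results plus genomic-control summary."""

    results: pd.DataFrame
    lambda_gc: float
    thresholds: GwasThresholds
    n_qualifying: int


def single_variant_scan(
    variants,
    samples,
    comparison,
    covariate_columns: Sequence[str],
    mac_min: int = 20,
    thresholds: GwasThresholds = GwasThresholds(),
    refit_p_max: float = 1e-4,
    annotation=None,
) -> SingleVariantScanResult:
    """Score-test every qualifying variant for one comparison.

    OR and 95% CI come from the one-step score approximation
    (beta = U/V, se = V^-1/2); variants passing ``refit_p_max`` are
    refitted with Firth logistic regression for finite, reportable
    estimates under near-separation (``test_used`` records which).
    """
    sel1, sel2 = comparison
    m1, m2 = samples.group_mask(sel1), samples.group_mask(sel2)
    if np.any(m1 & m2):
        raise ValueError(f"comparison groups {sel1!r}/{sel2!r} overlap")
    sub = m1 | m2
    y = m1[sub].astype(np.float64)
    idx = variants.sample_index(samples.sample_ids[sub])
    mac = variants.mac(idx)
    qualify = mac > mac_min
    if annotation is not None and annotation.excluded is not None:
        qualify &= ~annotation.excluded
    qidx = np.where(qualify)[0]
    if qidx.size == 0:
        logger.warning("no variants pass MAC > %d in the tested individuals", mac_min)
        return SingleVariantScanResult(
            results=pd.DataFrame(), lambda_gc=float("nan"),
            thresholds=thresholds, n_qualifying=0,
        )

    dosage = variants.dosage(idx)[:, qidx]
    cov = samples.covariate_matrix(covariate_columns, mask=sub)
    engine = LogisticScoreEngine(y, cov)
    z, p = engine.test(dosage)
    beta, se = engine.effect_estimates(dosage)

    aaf1 = dosage[y == 1].mean(axis=0) / 2.0
    aaf0 = dosage[y == 0].mean(axis=0) / 2.0

    test_used = np.full(qidx.size, "score", dtype=object)
    refit = np.where(p < refit_p_max)[0]
    for j in refit:
        X = np.column_stack([np.ones(len(y)), dosage[:, j], cov])
        params, bse, converged = firth_logistic(y, X)
        if converged:
            beta[j], se[j] = params[1], bse[1]
            test_used[j] = "firth"

    zcrit = stats.norm.isf(0.025)
    df = pd.DataFrame(
        {
            "variant_id": variants.variants["variant_id"].to_numpy()[qidx],
            "chrom": variants.variants["chrom"].to_numpy()[qidx],
            "pos": variants.variants["pos"].to_numpy()[qidx],
            "mac": mac[qidx],
            "aaf_group1": aaf1,
            "aaf_group2": aaf0,
            "beta": beta,
            "se": se,
            "or": np.exp(beta),
            "ci95_low": np.exp(beta - zcrit * se),
            "ci95_high": np.exp(beta + zcrit * se),
            "z": z,
            "p": p,
            "test_used": test_used,
        }
    )
    df["significant"] = df["p"] < thresholds.genome_wide
    df["significant_conservative"] = df["p"] < thresholds.conservative
    return SingleVariantScanResult(
        results=df,
        lambda_gc=lambda_gc(df["p"].to_numpy()),
        thresholds=thresholds,
        n_qualifying=int(qidx.size),
    )
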