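"""Analytic case-control single-variant power calculation.

Design-stage power for the 1-df allelic test of a case/control allele
frequency difference, under a multiplicative (per-allele, OR-scale)
disease model with HWE in the population and *population-based*
(unscreened) controls whose genotype frequencies equal the population's.

The machinery: given risk-allele frequency p, prevalence K and
per-allele odds ratio r, solve for the baseline genotype odds so the
population-average risk equals K; case genotype frequencies follow by
Bayes, controls keep population frequencies.  Power for the allele
frequency difference uses the normal approximation with the variance
under the alternative, against a one-tailed critical value at alpha by
default (the design convention of classic epidemiological detectable-OR
calculations; a two-tailed option is provided).  The reported detectable
OR is on the allelic (cross-product) scale — the quantity a 2x2 table
estimates, slightly attenuated relative to the per-allele model OR
because unscreened controls include cases.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable

import numpy as np
from scipy import optimize, stats

__all__ = [
    "PowerQuery",
    "PowerResult",
    "case_allele_frequency",
    "power_at_or",
    "or_for_power",
    "power_grid",
    "simulate_power",
]


@dataclasses.dataclass(frozen=True)
class PowerQuery:
    """Design parameters of the power calculation."""

    prevalence: float
    n_case: int
    n_control: int
    maf: float
    alpha: float
    target_power: float = 0.80
    tails: int = 1

    def __post_init__(self):
        for name in ("prevalence", "maf", "alpha", "target_power"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.n_case <= 0 or self.n_control <= 0:
            raise ValueError("sample sizes must be positive")
        if self.tails not in (1, 2):
            raise ValueError("tails must be 1 or 2")


@dataclasses.dataclass
class PowerResult:
    """Detectable odds ratio at the target power."""

    query: PowerQuery
    or_at_target: float  # allelic (cross-product) scale — as reported
    or_per_allele: float  # multiplicative model scale
    achieved_power: float

    def power_at(self, or_per_allele: float) -> float:
        return power_at_or(self.query, or_per_allele)


def _genotype_freqs(p: float) -> np.ndarray:
    return np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])


def case_genotype_frequencies(maf: float, prevalence: float, or_per_allele: float):
    """Case genotype frequencies under the prevalence-scaled
    multiplicative odds model; also returns population frequencies."""
    if or_per_allele <= 0:
        raise ValueError("odds ratio must be positive")
    f = _genotype_freqs(maf)
    rr = np.array([1.0, or_per_allele, or_per_allele**2])

    def mean_risk(odds0):
        o = odds0 * rr
        return float(f @ (o / (1.0 + o))) - prevalence

    odds0 = optimize.brentq(mean_risk, 1e-15, 1e9, rtol=1e-14, maxiter=200)
    risk = odds0 * rr / (1.0 + odds0 * rr)
    f_case = f * risk / (f @ risk)
    return f_case, f


def case_allele_frequency(maf: float, prevalence: float, or_per_allele: float) -> float:
    f_case, _ = case_genotype_frequencies(maf, prevalence, or_per_allele)
    return float(0.5 * f_case[1] + f_case[2])


def allelic_or(p_case: float, p_control: float) -> float:
    """Cross-product odds ratio of the case/control allele frequencies."""
    return (p_case / (1 - p_case)) / (p_control / (1 - p_control))


def power_at_or(q: PowerQuery, or_per_allele: float) -> float:
    """Power of the allele-frequency-difference test at a per-allele OR.

    Normal approximation with the alternative-hypothesis variance of the
    frequency difference; controls carry population frequencies.  At
    r = 1 the power equals the test size.
    """
    p1 = case_allele_frequency(q.maf, q.prevalence, or_per_allele)
    p2 = q.maf
    n1, n2 = 2.0 * q.n_case, 2.0 * q.n_control
    se = np.sqrt(p1 * (1 - p1) / n1 + p2 * (1 - p2) / n2)
    if q.tails == 1:
        zc = stats.norm.isf(q.alpha)
        return float(stats.norm.sf(zc - (p1 - p2) / se))
    zc = stats.norm.isf(q.alpha / 2.0)
    mu = (p1 - p2) / se
    return float(stats.norm.sf(zc - mu) + stats.norm.cdf(-zc - mu))


def or_for_power(q: PowerQuery, r_max: float = 100.0, tol: float = 1e-6) -> PowerResult:
    """Invert :func:`power_at_or` for the detectable OR at target power."""
    f = lambda r: power_at_or(q, r) - q.target_power
    if f(r_max) < 0:
        raise ValueError(
            f"target power {q.target_power} unreachable below OR {r_max}"
        )
    r = optimize.brentq(f, 1.0 + 1e-9, r_max, xtol=1e-12, rtol=1e-14)
    achieved = power_at_or(q, r)
    if abs(achieved - q.target_power) > tol:
        raise RuntimeError("power inversion did not reach tolerance")
    p1 = case_allele_frequency(q.maf, q.prevalence, r)
    return PowerResult(
        query=q,
        or_at_target=float(allelic_or(p1, q.maf)),
        or_per_allele=float(r),
        achieved_power=float(achieved),
    )


#: the emulated study's design grid: three phenotype groups x two MAFs x
#: two significance levels (genome-wide and conservative 7-comparison).
STUDY_PHENOTYPES = {
    "BD": dict(prevalence=0.01, n_case=1500),
    "SZ": dict(prevalence=0.01, n_case=3000),
    "SZ+BD": dict(prevalence=0.02, n_case=4500),
}
STUDY_N_CONTROL = 11_000
STUDY_ALPHAS = (5e-9, 5e-9 / 7)
STUDY_MAFS = (0.01, 0.05)


def power_grid(
    phenotypes=None,
    mafs: Iterable[float] = STUDY_MAFS,
    alphas: Iterable[float] = STUDY_ALPHAS,
    n_control: int = STUDY_N_CONTROL,
    target_power: float = 0.80,
):
    """Detectable-OR grid over phenotypes x MAFs x significance levels."""
    import pandas as pd

    phenotypes = phenotypes or STUDY_PHENOTYPES
    rows = []
    for name, spec in phenotypes.items():
        for maf in mafs:
            for alpha in alphas:
                q = PowerQuery(
                    prevalence=spec["prevalence"],
                    n_case=spec["n_case"],
                    n_control=n_control,
                    maf=maf,
                    alpha=alpha,
                    target_power=target_power,
                )
                res = or_for_power(q)
                rows.append(
                    {
                        "phenotype": name,
                        "maf": maf,
                        "alpha": alpha,
                        "n_case": spec["n_case"],
                        "n_control": n_control,
                        "prevalence": spec["prevalence"],
                        "or_detectable": res.or_at_target,
                        "or_per_allele": res.or_per_allele,
                    }
                )
    return pd.DataFrame(rows)


def simulate_power(
    q: PowerQuery, or_per_allele: float, n_reps: int = 10_000, seed: int = 0
) -> float:
    """Empirical rejection rate of the design-variance allelic statistic.

    Draws case genotype counts from the model's case genotype
    frequencies and control allele counts from the population binomial,
    then applies the same statistic the analytic formula models (the
    frequency difference standardised by its design-alternative SE).
    """
    rng = np.random.default_rng(seed)
    f_case, _ = case_genotype_frequencies(q.maf, q.prevalence, or_per_allele)
    p1 = 0.5 * f_case[1] + f_case[2]
    p2 = q.maf
    n1, n2 = 2 * q.n_case, 2 * q.n_control
    se = np.sqrt(p1 * (1 - p1) / n1 + p2 * (1 - p2) / n2)
    g = rng.multinomial(q.n_case, f_case, size=n_reps)
    ac_case = g[:, 1] + 2 * g[:, 2]
    ac_ctrl = rng.binomial(n2, p2, size=n_reps)
    d = ac_case / n1 - ac_ctrl / n2
    z = d / se
    if q.tails == 1:
        return float(np.mean(z > stats.norm.isf(q.alpha)))
    return float(np.mean(np.abs(z) > stats.norm.isf(q.alpha / 2.0)))
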