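"""Genome-wide multi-size sliding-window weighted burden scan.

Windows of several sizes (default 5-50 kb, half-window step) tile each
chromosome; each window's MAF-weighted burden is score-tested against
the outcome under the shared covariate-adjusted logistic null.  The
family-wise threshold comes from a permutation estimate of the effective
number of tests: outcome residuals are permuted within strata of the
covariate-only linear predictor, the genome-wide minimum p is recorded
per permutation, and 0.05 divided by its empirical 5th percentile is the
effective test count.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .burden import (
    BurdenDesign,
    analysis_mask,
    burden_logistic_test,
    lambda_gc,
    total_burden_covariate,
    variant_weight,
)
from .score import LogisticScoreEngine

__all__ = [
    "WindowGrid",
    "build_window_grid",
    "scan",
    "ScanResult",
    "effective_tests_from_minp",
    "dissect_window",
    "WindowDissection",
]

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_SIZES_KB = (5, 10, 15, 20, 25, 50)


@dataclasses.dataclass
class WindowGrid:
    """Sliding windows per chromosome (0-based half-open)."""

    windows: pd.DataFrame  # chrom, start, end, size
    sizes: Sequence[int]
    step_fraction: float

    def __len__(self) -> int:
        return len(self.windows)


def build_window_grid(
    chrom_lengths: Dict[str, int],
    sizes_kb: Sequence[int] = DEFAULT_WINDOW_SIZES_KB,
    step_fraction: float = 0.5,
) -> WindowGrid:
    """Tile each chromosome with windows of every size.

    For size ``s`` windows start at 0, s*f, 2s*f, ... (f = step
    fraction); the last window is clipped to the chromosome end.  Sizes
    exceeding a chromosome's length are skipped for it with a warning.
    """
    if not (0 < step_fraction <= 1):
        raise ValueError("step_fraction must lie in (0, 1]")
    rows = []
    for chrom, length in chrom_lengths.items():
        for size_kb in sizes_kb:
            size = int(size_kb * 1000)
            if size <= 0:
                raise ValueError("window sizes must be positive")
            if size > length:
                logger.warning(
                    "window size %d kb exceeds %s length %d; skipped",
                    size_kb,
                    chrom,
                    length,
                )
                continue
            step = max(int(size * step_fraction), 1)
            for start in range(0, length, step):
                end = min(start + size, length)
                rows.append((chrom, start, end, size))
    return WindowGrid(
        windows=pd.DataFrame(rows, columns=["chrom", "start", "end", "size"]),
        sizes=list(sizes_kb),
        step_fraction=step_fraction,
    )


def effective_tests_from_minp(minp: np.ndarray, family_alpha: float = 0.05) -> float:
    """Effective test count from per-permutation genome-wide minimum
    p-values: alpha divided by the empirical alpha-quantile of min-p."""
    minp = np.asarray(minp, dtype=np.float64)
    if minp.size == 0:
        raise ValueError("no permutation minima supplied")
    q = np.quantile(minp, family_alpha)
    q = max(q, np.nextafter(0, 1))
    return float(family_alpha / q)


@dataclasses.dataclass
class ScanResult:
    """Window-scan outcome: per-window tests plus calibrated thresholds."""

    windows: pd.DataFrame
    n_effective: float
    threshold: float
    lambda_gc: float
    n_perm: int
    perm_minp: np.ndarray
    threshold_all_analyses: Optional[float] = None

    @property
    def min_p(self) -> float:
        tested = self.windows[self.windows["tested"]]
        return float(tested["p"].min())

    def min_p_window(self) -> pd.Series:
        tested = self.windows[self.windows["tested"]]
        return tested.loc[tested["p"].idxmin()]


def _window_burdens(dosage, weights, positions, chrom_col, grid):
    """Burden matrix (n x n_windows) and per-window analysis-set variant
    counts.  Relies on variants being position-sorted within chromosome."""
    n = dosage.shape[0]
    wdf = grid.windows
    B = np.zeros((n, len(wdf)))
    counts = np.zeros(len(wdf), dtype=np.int64)
    for chrom in wdf["chrom"].unique():
        vmask = chrom_col == chrom
        vidx = np.where(vmask)[0]
        pos0 = positions[vidx] - 1
        active = weights[vidx] > 0
        sub = wdf.index[wdf["chrom"] == chrom]
        lo = np.searchsorted(pos0, wdf.loc[sub, "start"].to_numpy(), side="left")
        hi = np.searchsorted(pos0, wdf.loc[sub, "end"].to_numpy(), side="left")
        for w, (a, b) in zip(sub, zip(lo, hi)):
            cols = vidx[a:b]
            counts[w] = int(active[a:b].sum())
            if cols.size:
                B[:, w] = dosage[:, cols] @ weights[cols]
    return B, counts


def scan(
    variants,
    annotation,
    samples,
    comparison,
    grid: WindowGrid,
    design: BurdenDesign,
    n_perm: int = 5000,
    seed: int = 0,
    with_metadata_pcs: bool = False,
    min_variants: int = 2,
    total_effective_tests: Optional[float] = None,
    family_alpha: float = 0.05,
) -> ScanResult:
    """Run the sliding-window burden scan for one comparison."""
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100 for a usable threshold")
    sel1, sel2 = comparison
    m1, m2 = samples.group_mask(sel1), samples.group_mask(sel2)
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

    cov = samples.covariate_matrix(
        design.covariate_columns(with_metadata_pcs), mask=sub
    )
    if design.include_total_burden:
        cov = np.column_stack([cov, total_burden_covariate(dosage, weights)])

    B, counts = _window_burdens(
        dosage,
        weights,
        variants.variants["pos"].to_numpy(),
        variants.variants["chrom"].to_numpy(),
        grid,
    )
    tested = counts >= min_variants
    n_skipped = int((~tested).sum())
    if n_skipped:
        logger.info("%d windows with <%d analysis-set variants skipped", n_skipped, min_variants)
    if not tested.any():
        raise ValueError("no window has enough analysis-set variants")

    engine = LogisticScoreEngine(y, cov)
    Bt = B[:, tested]
    z, p = engine.test(Bt)
    beta, se = engine.effect_estimates(Bt)

    # permutation null for the effective number of tests
    from scipy import stats as _st

    rng = np.random.default_rng(seed)
    V = engine.variance(Bt)
    sqrtV = np.sqrt(np.where(V > 0, V, np.inf))
    minp = np.empty(n_perm)
    block = max(1, int(5_000_000 // max(Bt.shape[0], 1)))
    done = 0
    while done < n_perm:
        nb = min(block, n_perm - done)
        R = engine.permuted_residuals(nb, rng)
        Zp = np.abs((R @ Bt) / sqrtV)
        minp[done : done + nb] = 2.0 * _st.norm.sf(Zp.max(axis=1))
        done += nb
    minp = np.clip(minp, np.nextafter(0, 1), 1.0)
    n_eff = min(effective_tests_from_minp(minp, family_alpha), float(tested.sum()))
    threshold = family_alpha / n_eff
    thr_all = (
        family_alpha / total_effective_tests if total_effective_tests else None
    )

    wdf = grid.windows.copy()
    wdf["n_variants"] = counts
    wdf["tested"] = tested
    for col in ("z", "p", "beta", "se"):
        wdf[col] = np.nan
    wdf.loc[tested, "z"] = z
    wdf.loc[tested, "p"] = p
    wdf.loc[tested, "beta"] = beta
    wdf.loc[tested, "se"] = se
    wdf["or"] = np.exp(wdf["beta"])
    wdf["significant"] = wdf["p"] < threshold
    if thr_all is not None:
        wdf["significant_all_analyses"] = wdf["p"] < thr_all
    lam = lambda_gc(wdf.loc[tested, "p"].to_numpy())
    return ScanResult(
        windows=wdf,
        n_effective=n_eff,
        threshold=threshold,
        lambda_gc=lam,
        n_perm=n_perm,
        perm_minp=minp,
        threshold_all_analyses=thr_all,
    )


@dataclasses.dataclass
class WindowDissection:
    """Secondary dissection of one window: burden test outside repeats,
    per-variant Fisher tests, and burden tests on the Fisher partition."""

    window: tuple
    non_repeat: Optional[object]
    fisher: pd.DataFrame
    nominal: Optional[object]
    non_nominal: Optional[object]
    notes: List[str]

    def to_dict(self) -> dict:
        def res(r):
            if r is None:
                return None
            return {
                "beta": r.beta,
                "se": r.se,
                "or": r.or_,
                "p": r.pvalue,
                "n_variants": r.n_variants,
                "method": r.method_used,
            }

        return {
            "window": list(self.window),
            "non_repeat_burden": res(self.non_repeat),
            "nominal_burden": res(self.nominal),
            "non_nominal_burden": res(self.non_nominal),
            "fisher": self.fisher.to_dict(orient="records"),
            "notes": self.notes,
        }


def dissect_window(
    variants,
    annotation,
    samples,
    comparison,
    window,
    design: BurdenDesign,
    with_metadata_pcs: bool = False,
) -> WindowDissection:
    """Dissect the most strongly associated window.

    (a) burden test restricted to non-repeat variants; (b) two-sided
    Fisher's exact allele-count test per variant; (c)/(d) burden tests on
    the nominally significant (Fisher p < 0.05) variants and on their
    complement.
    """
    from .burden import sample_burden
    from .single_variant import fisher_exact_allelic

    chrom, start, end = window
    sel1, sel2 = comparison
    m1, m2 = samples.group_mask(sel1), samples.group_mask(sel2)
    sub = m1 | m2
    y = m1[sub].astype(np.float64)
    idx = variants.sample_index(samples.sample_ids[sub])
    maf = variants.maf(idx)
    mask = analysis_mask(
        maf, variants.variants["is_snv"].to_numpy(), annotation.excluded, design
    )
    vdf = variants.variants
    in_window = (
        (vdf["chrom"].to_numpy() == chrom)
        & (vdf["pos"].to_numpy() - 1 >= start)
        & (vdf["pos"].to_numpy() - 1 < end)
    )
    widx = np.where(in_window & mask)[0]
    weights = np.zeros(variants.n_variants)
    weights[mask] = variant_weight(maf[mask], design.weights)
    dosage = variants.dosage(idx)
    cov = samples.covariate_matrix(
        design.covariate_columns(with_metadata_pcs), mask=sub
    )
    if design.include_total_burden:
        cov = np.column_stack([cov, total_burden_covariate(dosage, weights)])

    notes: List[str] = []

    def burden_res(members, label):
        if members.size == 0:
            notes.append(f"{label}: no variants; test not run")
            return None
        res = burden_logistic_test(y, sample_burden(dosage, weights, members), cov)
        res.label = label
        res.n_variants = int(members.size)
        return res

    from .annotation import ANY_REPEAT

    repeat_idx = annotation.members("repeat", ANY_REPEAT)
    non_repeat = np.setdiff1d(widx, repeat_idx)
    res_a = burden_res(non_repeat, "non_repeat")

    n1 = int(m1[sub].sum())
    n2 = int(m2[sub].sum())
    g1 = dosage[y == 1][:, widx]
    g2 = dosage[y == 0][:, widx]
    ac1 = g1.sum(axis=0).astype(int)
    ac2 = g2.sum(axis=0).astype(int)
    rows = []
    for j, v in enumerate(widx):
        or_, p = fisher_exact_allelic(ac1[j], n1, ac2[j], n2)
        rows.append(
            {
                "variant_id": vdf["variant_id"].iloc[v],
                "pos": int(vdf["pos"].iloc[v]),
                "ac_group1": int(ac1[j]),
                "an_group1": 2 * n1,
                "ac_group2": int(ac2[j]),
                "an_group2": 2 * n2,
                "or": or_,
                "p": p,
            }
        )
    fisher = pd.DataFrame(rows)
    if len(fisher):
        nominal_mask = fisher["p"].to_numpy() < 0.05
        res_c = burden_res(widx[nominal_mask], "fisher_nominal")
        res_d = burden_res(widx[~nominal_mask], "fisher_non_nominal")
    else:
        notes.append("window contains no analysis-set variants")
        res_c = res_d = None
    return WindowDissection(
        window=(chrom, start, end),
        non_repeat=res_a,
        fisher=fisher,
        nominal=res_c,
        non_nominal=res_d,
        notes=notes,
    )
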