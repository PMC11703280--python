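"""Singleton protein-truncating-variant burden tests.

Singletons are defined on the designated unrelated samples (allele count
exactly 1 there, regardless of copies among relatives); PTVs are the
frameshift / stop-gained / splice-acceptor / splice-donor consequence
classes.  Genes with more than ``gene_min`` PTV singletons are tested by
logistic regression of case status on the per-sample PTV singleton
count, adjusting for genetic PCs, sex and the individual's genome-wide
total singleton count; gene sets sum the per-gene counts first.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .burden import burden_logistic_test

__all__ = [
    "PTV_CONSEQUENCES",
    "PtvCatalog",
    "GeneResult",
    "build_ptv_catalog",
    "gene_burden_test",
    "geneset_burden_test",
]

logger = logging.getLogger(__name__)

PTV_CONSEQUENCES = frozenset(
    ["frameshift", "stop_gained", "splice_acceptor", "splice_donor"]
)

GENE_MIN_PTV_SINGLETONS = 10


@dataclasses.dataclass
class PtvCatalog:
    """Singleton flags and PTV bookkeeping for gene-level tests."""

    variant_gene: pd.DataFrame  # variant_id, gene_id, consequence, is_ptv
    singleton: np.ndarray  # per-variant flag (unrelated-sample AC == 1)
    gene_ptv_counts: pd.Series  # gene -> number of singleton PTVs
    sample_ptv_matrix: Dict[str, np.ndarray]  # gene -> per-sample counts
    total_singletons: np.ndarray  # per-sample count of ALL singleton alleles
    sample_ids: np.ndarray
    gene_min: int = GENE_MIN_PTV_SINGLETONS

    def tested_genes(self):
        return self.gene_ptv_counts[self.gene_ptv_counts > self.gene_min].index.tolist()

    def geneset_counts(self, genes: Sequence[str]) -> np.ndarray:
        out = np.zeros(len(self.sample_ids))
        for g in genes:
            if g in self.sample_ptv_matrix:
                out += self.sample_ptv_matrix[g]
        return out


@dataclasses.dataclass
class GeneResult:
    """One gene or gene-set burden test outcome."""

    gene_id: str
    n_ptv_singletons: int
    tested: bool
    or_: float = float("nan")
    beta: float = float("nan")
    se: float = float("nan")
    p: float = float("nan")
    method_used: str = "not_tested"
    n_case: int = 0
    n_control: int = 0


def build_ptv_catalog(
    variants,
    consequences: pd.DataFrame,
    unrelated_ids: Sequence[str],
    gene_min: int = GENE_MIN_PTV_SINGLETONS,
) -> PtvCatalog:
    """Assemble singleton flags, per-gene PTV counts and the per-sample
    total-singleton covariate.

    ``consequences`` holds variant_id / gene_id / consequence rows;
    variants absent from it count as "other".  A variant annotated to
    several genes contributes once per gene.
    """
    dup = consequences.groupby(["variant_id", "gene_id"])["consequence"].nunique()
    if (dup > 1).any():
        bad = dup[dup > 1].index.tolist()[:5]
        raise ValueError(f"conflicting consequences for variant/gene pairs: {bad}")

    unrel_idx = variants.sample_index(list(unrelated_ids))
    g = variants.genotypes[unrel_idx]
    ac = np.where(g == -1, 0, g).sum(axis=0, dtype=np.int64)
    singleton = ac == 1

    # per-sample total singleton alleles (all singletons, not PTV-only)
    sidx = np.where(singleton)[0]
    dos_all = variants.dosage()[:, sidx]
    total_singletons = dos_all.sum(axis=1)

    vid_to_col = {v: j for j, v in enumerate(variants.variants["variant_id"])}
    cons = consequences.copy()
    cons = cons[cons["gene_id"].ne(".") & cons["gene_id"].notna()]
    cons["is_ptv"] = cons["consequence"].isin(PTV_CONSEQUENCES)

    sample_ptv: Dict[str, np.ndarray] = {}
    gene_counts = {}
    dosage = variants.dosage()
    for gene, grp in cons[cons["is_ptv"]].groupby("gene_id"):
        cols = np.array(
            [vid_to_col[v] for v in grp["variant_id"] if v in vid_to_col],
            dtype=np.intp,
        )
        cols = cols[singleton[cols]]
        gene_counts[gene] = int(cols.size)
        if cols.size:
            sample_ptv[gene] = dosage[:, cols].sum(axis=1)
    return PtvCatalog(
        variant_gene=cons[["variant_id", "gene_id", "consequence", "is_ptv"]],
        singleton=singleton,
        gene_ptv_counts=pd.Series(gene_counts, dtype=int).sort_index(),
        sample_ptv_matrix=sample_ptv,
        total_singletons=total_singletons,
        sample_ids=variants.sample_ids,
        gene_min=gene_min,
    )


def gene_burden_test(
    catalog: PtvCatalog,
    gene: str,
    samples,
    comparison=("sz_bd", "controls_all"),
    covariate_columns: Optional[Sequence[str]] = None,
    method: str = "wald",
) -> GeneResult:
    """Burden-test one gene's singleton PTV count against case status."""
    n_ptv = int(catalog.gene_ptv_counts.get(gene, 0))
    if n_ptv <= catalog.gene_min:
        return GeneResult(gene_id=gene, n_ptv_singletons=n_ptv, tested=False)
    if covariate_columns is None:
        covariate_columns = [f"pc{i}" for i in range(1, 11)] + ["sex"]
    counts = catalog.sample_ptv_matrix[gene]
    case_mask = samples.group_mask(comparison[0])
    control_mask = samples.group_mask(comparison[1])
    sub = case_mask | control_mask
    y = case_mask[sub].astype(np.float64)
    cov = np.column_stack(
        [
            samples.covariate_matrix(covariate_columns, mask=sub),
            catalog.total_singletons[sub],
        ]
    )
    res = burden_logistic_test(y, counts[sub], cov, method=method)
    return GeneResult(
        gene_id=gene,
        n_ptv_singletons=n_ptv,
        tested=True,
        or_=res.or_,
        beta=res.beta,
        se=res.se,
        p=res.pvalue,
        method_used=res.method_used,
        n_case=int(y.sum()),
        n_control=int((1 - y).sum()),
    )


def geneset_burden_test(
    catalog: PtvCatalog,
    genes: Sequence[str],
    samples,
    comparison=("sz_bd", "controls_all"),
    covariate_columns: Optional[Sequence[str]] = None,
    set_name: str = "gene_set",
    method: str = "wald",
) -> GeneResult:
    """Burden-test the summed singleton PTV count over a gene set."""
    if len(genes) == 0:
        raise ValueError("gene set is empty")
    counts = catalog.geneset_counts(genes)
    n_ptv = int(sum(catalog.gene_ptv_counts.get(g, 0) for g in genes))
    if n_ptv == 0:
        return GeneResult(gene_id=set_name, n_ptv_singletons=0, tested=False)
    if covariate_columns is None:
        covariate_columns = [f"pc{i}" for i in range(1, 11)] + ["sex"]
    case_mask = samples.group_mask(comparison[0])
    control_mask = samples.group_mask(comparison[1])
    sub = case_mask | control_mask
    y = case_mask[sub].astype(np.float64)
    cov = np.column_stack(
        [
            samples.covariate_matrix(covariate_columns, mask=sub),
            catalog.total_singletons[sub],
        ]
    )
    res = burden_logistic_test(y, counts[sub], cov, method=method)
    return GeneResult(
        gene_id=set_name,
        n_ptv_singletons=n_ptv,
        tested=True,
        or_=res.or_,
        beta=res.beta,
        se=res.se,
        p=res.pvalue,
        method_used=res.method_used,
        n_case=int(y.sum()),
        n_control=int((1 - y).sum()),
    )
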