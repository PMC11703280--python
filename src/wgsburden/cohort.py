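"""Core in-memory containers: genotypes plus per-sample metadata.

The genotype substrate is a dense alt-allele dosage matrix (samples x
variants, int8, hard calls; -1 marks a missing genotype).  WGS-scale data
would use a sparse or chunked layout, but the analyses here aggregate over
variants, and a dense matrix keeps every burden computation a plain
matrix-vector product.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

__all__ = ["VariantTable", "SampleFrame", "GROUP_SELECTORS"]

MISSING = -1


@dataclasses.dataclass
class VariantTable:
    """Bi-allelic variant records with per-sample alt-allele dosages.

    Attributes
    ----------
    variants : pandas.DataFrame
        One row per variant with columns ``variant_id``, ``chrom``,
        ``pos`` (1-based, as in VCF), ``ref``, ``alt``, ``is_snv``.
    genotypes : numpy.ndarray
        ``(n_samples, n_variants)`` int8 dosage matrix with entries in
        {0, 1, 2} or :data:`MISSING`.
    sample_ids : numpy.ndarray
        Sample identifiers aligned with the rows of ``genotypes``.
    """

    variants: pd.DataFrame
    genotypes: np.ndarray
    sample_ids: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        if self.genotypes.shape != (len(self.sample_ids), len(self.variants)):
            raise ValueError(
                f"genotype matrix shape {self.genotypes.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variants)} variants"
            )
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.genotypes.shape[1]

    def sample_index(self, sample_ids) -> np.ndarray:
        """Row indices of ``sample_ids`` in the genotype matrix."""
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in lookup]
        if missing:
            raise KeyError(f"samples not in VariantTable: {missing[:5]}")
        return np.fromiter((lookup[s] for s in sample_ids), dtype=np.intp)

    def dosage(self, sample_mask=None, max_missing_rate: float = 0.05) -> np.ndarray:
        """Float dosage matrix for the selected samples.

        Missing genotypes are counted as 0 alt alleles; variants whose
        missingness exceeds ``max_missing_rate`` are reported in a warning
        (they are retained — filtering is the caller's decision).
        """
        g = self.genotypes if sample_mask is None else self.genotypes[sample_mask]
        miss = g == MISSING
        rate = miss.mean(axis=0) if g.shape[0] else np.zeros(g.shape[1])
        n_bad = int((rate > max_missing_rate).sum())
        if n_bad:
            warnings.warn(
                f"{n_bad} variants exceed missingness {max_missing_rate:g}; "
                "missing genotypes are counted as 0 alt alleles",
                stacklevel=2,
            )
        out = g.astype(np.float64)
        if miss.any():
            out[miss] = 0.0
        return out

    def alt_allele_frequency(self, sample_mask=None) -> np.ndarray:
        """Alt-allele frequency per variant over the selected samples."""
        g = self.genotypes if sample_mask is None else self.genotypes[sample_mask]
        called = g != MISSING
        ac = np.where(called, g, 0).sum(axis=0, dtype=np.int64)
        an = 2 * called.sum(axis=0, dtype=np.int64)
        with np.errstate(invalid="ignore", divide="ignore"):
            aaf = np.where(an > 0, ac / np.maximum(an, 1), np.nan)
        return aaf

    def maf(self, sample_mask=None) -> np.ndarray:
        aaf = self.alt_allele_frequency(sample_mask)
        return np.minimum(aaf, 1.0 - aaf)

    def mac(self, sample_mask=None) -> np.ndarray:
        """Minor allele count per variant over the selected samples."""
        g = self.genotypes if sample_mask is None else self.genotypes[sample_mask]
        called = g != MISSING
        ac = np.where(called, g, 0).sum(axis=0, dtype=np.int64)
        an = 2 * called.sum(axis=0, dtype=np.int64)
        return np.minimum(ac, an - ac)

    @classmethod
    def from_vcf(cls, path) -> "VariantTable":
        """Load bi-allelic variants with GT fields from a VCF (4.2)."""
        from cyvcf2 import VCF

        vcf = VCF(str(path), gts012=True)
        sample_ids = np.array(vcf.samples, dtype=object)
        rows = []
        dosages = []
        for rec in vcf:
            if len(rec.ALT) != 1:
                raise ValueError(
                    f"multi-allelic record at {rec.CHROM}:{rec.POS}; "
                    "split to bi-allelic sites first"
                )
            rows.append(
                (
                    rec.ID or f"{rec.CHROM}:{rec.POS}:{rec.REF}:{rec.ALT[0]}",
                    rec.CHROM,
                    rec.POS,
                    rec.REF,
                    rec.ALT[0],
                    len(rec.REF) == 1 and len(rec.ALT[0]) == 1,
                )
            )
            gt = rec.gt_types.astype(np.int8)  # 0,1,2, 3=unknown with gts012
            gt[gt == 3] = MISSING
            dosages.append(gt)
        vcf.close()
        variants = pd.DataFrame(
            rows, columns=["variant_id", "chrom", "pos", "ref", "alt", "is_snv"]
        )
        geno = (
            np.stack(dosages, axis=1)
            if dosages
            else np.empty((len(sample_ids), 0), dtype=np.int8)
        )
        return cls(variants=variants, genotypes=geno, sample_ids=sample_ids)


# Named sample-group selectors used by comparisons throughout the pipeline.
GROUP_SELECTORS = {
    "bd": lambda df: (df["phenotype"] == "BD").to_numpy(),
    "sz": lambda df: (df["phenotype"] == "SZ").to_numpy(),
    "sz_bd": lambda df: df["phenotype"].isin(["BD", "SZ"]).to_numpy(),
    "controls_internal": lambda df: (
        (df["phenotype"] == "CONTROL") & (df["study"] == "internal")
    ).to_numpy(),
    "controls_external": lambda df: (
        (df["phenotype"] == "CONTROL") & (df["study"] == "external")
    ).to_numpy(),
    "controls_all": lambda df: (df["phenotype"] == "CONTROL").to_numpy(),
}


class SampleFrame:
    """Per-sample metadata: phenotype, study, covariates and QC metrics.

    Thin wrapper over a :class:`pandas.DataFrame` indexed by ``sample_id``
    that validates required columns and provides named group masks.
    """

    REQUIRED = ("study", "phenotype", "sex")

    def __init__(self, df: pd.DataFrame):
        df = df.copy()
        if "sample_id" in df.columns:
            df = df.set_index("sample_id")
        for col in self.REQUIRED:
            if col not in df.columns:
                raise ValueError(f"sample table missing required column {col!r}")
        bad = set(df["phenotype"].unique()) - {"BD", "SZ", "CONTROL"}
        if bad:
            raise ValueError(f"unknown phenotype labels: {sorted(bad)}")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    @property
    def sample_ids(self) -> np.ndarray:
        return self.df.index.to_numpy(dtype=object)

    def group_mask(self, selector: str) -> np.ndarray:
        try:
            return GROUP_SELECTORS[selector](self.df)
        except KeyError:
            raise KeyError(
                f"unknown group selector {selector!r}; "
                f"known: {sorted(GROUP_SELECTORS)}"
            ) from None

    def covariate_matrix(self, columns, mask=None, names_out=None) -> np.ndarray:
        """Numeric covariate matrix; ``batch`` is one-hot coded
        (reference level dropped).

        ``mask`` restricts to a sample subset *before* dummy coding, so
        levels absent from the subset contribute no (all-zero) columns;
        constant columns within the subset are dropped.  ``names_out``,
        if a list, receives the emitted column names.
        """
        df = self.df if mask is None else self.df.loc[mask]
        blocks, names = [], []
        for col in columns:
            if col not in df.columns:
                raise KeyError(f"covariate column {col!r} not in sample table")
            series = df[col]
            if col == "batch" or series.dtype == object:
                dummies = pd.get_dummies(series, prefix=col, drop_first=True)
                for c in dummies.columns:
                    v = dummies[c].to_numpy(dtype=np.float64)
                    if np.ptp(v) > 0:
                        blocks.append(v[:, None])
                        names.append(str(c))
            else:
                v = series.to_numpy(dtype=np.float64)[:, None]
                blocks.append(v)
                names.append(col)
        if names_out is not None:
            names_out[:] = names
        if not blocks:
            return np.empty((len(df), 0))
        return np.hstack(blocks)

    @classmethod
    def read_tsv(cls, path) -> "SampleFrame":
        return cls(pd.read_csv(path, sep="\t", dtype={"sample_id": str}))

    def write_tsv(self, path) -> None:
        self.df.reset_index().rename(columns={"index": "sample_id"}).to_csv(
            path, sep="\t", index=False
        )
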