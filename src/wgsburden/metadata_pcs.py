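"""Sequencing-metadata principal components.

Per-sample sequencing QC metrics (mean depth, contamination, library
proxies) carry the technical signature of how and where a sample was
sequenced.  Their leading principal components, used as nuisance
covariates, can absorb differential-calling artifacts that differ
between jointly analysed studies.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import List, Sequence

import numpy as np
import pandas as pd

__all__ = ["MetricMatrix", "MetadataPCs", "build_metric_matrix", "compute_metadata_pcs"]

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class MetricMatrix:
    """Z-standardised samples x metrics matrix."""

    values: np.ndarray
    metric_names: List[str]
    sample_ids: np.ndarray
    means: np.ndarray
    sds: np.ndarray


@dataclasses.dataclass
class MetadataPCs:
    """Top-k metadata PC scores with loadings and variance fractions."""

    scores: pd.DataFrame  # sample_id index, columns mpc1..mpck
    loadings: pd.DataFrame  # metrics x components
    explained_variance_ratio: np.ndarray

    @property
    def k(self) -> int:
        return self.scores.shape[1]


def build_metric_matrix(samples, metric_columns: Sequence[str]) -> MetricMatrix:
    """Assemble and z-standardise the QC-metric matrix.

    ``samples`` is a SampleFrame or a DataFrame.  Missing entries are
    imputed to the column mean before standardisation (count logged);
    constant columns are dropped with a warning.
    """
    df = samples.df if hasattr(samples, "df") else samples
    cols, mats = [], []
    for col in metric_columns:
        if col not in df.columns:
            raise KeyError(f"metric column {col!r} not in sample table")
        v = pd.to_numeric(df[col], errors="raise").to_numpy(dtype=np.float64)
        n_missing = int(np.isnan(v).sum())
        if n_missing:
            logger.info("metric %s: imputing %d missing values to mean", col, n_missing)
            v = np.where(np.isnan(v), np.nanmean(v), v)
        if np.ptp(v) == 0.0:
            logger.warning("metric %s is constant; dropped", col)
            continue
        cols.append(col)
        mats.append(v)
    if len(cols) < 2:
        raise ValueError(
            f"need >=2 usable (non-constant) metrics, got {len(cols)}: {cols}"
        )
    m = np.column_stack(mats)
    means = m.mean(axis=0)
    sds = m.std(axis=0, ddof=0)
    z = (m - means) / sds
    return MetricMatrix(
        values=z,
        metric_names=cols,
        sample_ids=df.index.to_numpy(dtype=object),
        means=means,
        sds=sds,
    )


def compute_metadata_pcs(m: MetricMatrix, k: int = 4) -> MetadataPCs:
    """Top-k principal components of the standardised metric matrix.

    Deterministic up to sign; the sign convention (the largest-magnitude
    loading of each component is positive) makes the output fully
    reproducible across platforms.
    """
    z = m.values
    rank = int(np.linalg.matrix_rank(z - z.mean(axis=0)))
    if k > rank:
        raise ValueError(f"k={k} exceeds achievable rank {rank}")
    u, s, vt = np.linalg.svd(z - z.mean(axis=0), full_matrices=False)
    # sign convention: largest-|loading| entry positive per component
    for j in range(k):
        i = int(np.argmax(np.abs(vt[j])))
        if vt[j, i] < 0:
            vt[j] *= -1.0
            u[:, j] *= -1.0
    scores = u[:, :k] * s[:k]
    total_var = float((s**2).sum())
    evr = (s[:k] ** 2) / total_var if total_var > 0 else np.zeros(k)
    names = [f"mpc{i+1}" for i in range(k)]
    return MetadataPCs(
        scores=pd.DataFrame(scores, index=m.sample_ids, columns=names),
        loadings=pd.DataFrame(vt[:k].T, index=m.metric_names, columns=names),
        explained_variance_ratio=evr,
    )
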