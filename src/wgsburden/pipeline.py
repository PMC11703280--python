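"""Orchestration of the comparison groups and analysis types.

The study design tests seven sample-group comparisons (six case/control
pairs plus internal-vs-external controls) under four analysis types
(single-variant, PTV gene/gene-set, annotation-category burden, sliding
windows), each run with and/or without sequencing-metadata PCs.  This
module wires the analysis modules together over one dataset, writes
per-analysis TSVs plus a lambda_GC summary grid, and emits a manifest
for reproducibility.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .annotation import load_bed_track, annotate_variants
from .burden import BurdenDesign, run_category_scan
from .cohort import SampleFrame, VariantTable
from .metadata_pcs import build_metric_matrix, compute_metadata_pcs
from .ptv import build_ptv_catalog, gene_burden_test, geneset_burden_test
from .single_variant import single_variant_scan
from .windows import build_window_grid, scan as window_scan

__all__ = [
    "DEFAULT_COMPARISONS",
    "N_COMPARISONS",
    "DEFAULT_METRIC_COLUMNS",
    "AnalysisPlan",
    "run_plan",
    "sensitivity_report",
]

logger = logging.getLogger(__name__)

#: the seven comparison groups: six case/control pairs + control/control.
DEFAULT_COMPARISONS = (
    ("bd", "controls_all"),
    ("bd", "controls_internal"),
    ("sz", "controls_all"),
    ("sz", "controls_internal"),
    ("sz_bd", "controls_all"),
    ("sz_bd", "controls_internal"),
    ("controls_internal", "controls_external"),
)
#: single source of truth for the conservative-threshold divisor.
N_COMPARISONS = len(DEFAULT_COMPARISONS)

# four metrics -> four metadata PCs span the full metric space, so the
# depth-driven latent calling-quality factor is fully captured (the
# regime in which metadata-PC adjustment can absorb depth-driven
# differential calling); extra metrics such as gc_dropout can be added.
DEFAULT_METRIC_COLUMNS = (
    "depth_mean",
    "contamination",
    "insert_size",
    "base_quality",
)

ANALYSES = ("single_variant", "ptv", "category_scan", "window_scan")


def _internal_only(samples: SampleFrame, comparison) -> bool:
    sub = samples.group_mask(comparison[0]) | samples.group_mask(comparison[1])
    return bool((samples.df["study"].to_numpy()[sub] == "internal").all())


@dataclasses.dataclass
class AnalysisPlan:
    """What to run: comparisons x analyses x covariate modes."""

    comparisons: Sequence = DEFAULT_COMPARISONS
    analyses: Sequence[str] = ANALYSES
    with_metadata_pcs: str = "both"  # "true" | "false" | "both"
    n_metadata_pcs: int = 4
    metric_columns: Sequence[str] = DEFAULT_METRIC_COLUMNS
    window_sizes_kb: Sequence[int] = (5, 10, 15, 20, 25, 50)
    n_perm: int = 1000
    mac_min: int = 20
    gene_sets: Dict[str, Sequence[str]] = dataclasses.field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        for a in self.analyses:
            if a not in ANALYSES:
                raise ValueError(f"unknown analysis {a!r}; known: {ANALYSES}")
        if self.with_metadata_pcs not in ("true", "false", "both"):
            raise ValueError("with_metadata_pcs must be 'true', 'false' or 'both'")
        for sel1, sel2 in self.comparisons:
            pass  # validated against data at run time

    def modes(self) -> List[bool]:
        return {"true": [True], "false": [False], "both": [False, True]}[
            self.with_metadata_pcs
        ]


def load_inputs(paths: Dict[str, str]):
    """Load a real-format input bundle (VCF + TSVs + BEDs)."""
    variants = VariantTable.from_vcf(paths["vcf"])
    samples = SampleFrame.read_tsv(paths["samples"])
    atlas = None
    from .annotation import AnnotationAtlas

    atlas = AnnotationAtlas()
    for system in ("chrom_state", "cons_state", "repeat", "excluded"):
        if system in paths:
            load_bed_track(paths[system], system, atlas=atlas)
    consequences = (
        pd.read_csv(paths["consequences"], sep="\t")
        if "consequences" in paths
        else None
    )
    chrom_lengths = (
        variants.variants.groupby("chrom")["pos"].max().astype(int).to_dict()
    )
    return variants, samples, atlas, consequences, chrom_lengths


def run_plan(plan: AnalysisPlan, inputs, outdir) -> Path:
    """Execute the plan; one results TSV per comparison x analysis x mode.

    ``inputs`` is either a SyntheticCohort or a dict of file paths
    (keys: vcf, samples, chrom_state, cons_state, repeat, excluded,
    consequences).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if isinstance(inputs, dict):
        variants, samples, atlas, consequences, chrom_lengths = load_inputs(inputs)
        annotation = annotate_variants(variants, atlas)
    else:  # SyntheticCohort
        variants = inputs.variant_table
        samples = inputs.samples
        annotation = inputs.annotate()
        consequences = inputs.consequences
        chrom_lengths = inputs.truth["chrom_lengths"]

    config_repr = json.dumps(dataclasses.asdict(plan), default=str, sort_keys=True)
    manifest = {
        "package_version": __version__,
        "seed": plan.seed,
        "config_sha256": hashlib.sha256(config_repr.encode()).hexdigest(),
        "plan": json.loads(config_repr),
        "n_samples": int(len(samples)),
        "n_variants": int(variants.n_variants),
        "stages_completed": [],
    }

    def save_manifest():
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)

    save_manifest()

    # metadata PCs are attached once, used by any mode that asks for them
    mpc_cols: List[str] = []
    if any(plan.modes()):
        metric = build_metric_matrix(samples, plan.metric_columns)
        pcs = compute_metadata_pcs(metric, k=plan.n_metadata_pcs)
        for c in pcs.scores.columns:
            samples.df[c] = pcs.scores[c].to_numpy()
        mpc_cols = list(pcs.scores.columns)
        pcs.scores.to_csv(outdir / "metadata_pcs.tsv", sep="\t")
        pcs.loadings.to_csv(outdir / "metadata_pc_loadings.tsv", sep="\t")

    lambda_rows = []

    def stage(name):
        logger.info("stage: %s", name)
        manifest["stages_completed"].append(name)
        save_manifest()

    for comparison in plan.comparisons:
        sel1, sel2 = comparison
        cmp_name = f"{sel1}_vs_{sel2}"
        base_cov = [f"pc{i}" for i in range(1, 11)] + ["sex"]
        if _internal_only(samples, comparison):
            base_cov.append("batch")
        design = BurdenDesign(covariates=base_cov, metadata_pc_columns=mpc_cols)
        for mode in plan.modes():
            tag = "mpc" if mode else "base"
            try:
                if "category_scan" in plan.analyses:
                    res = run_category_scan(
                        variants, annotation, samples, comparison, design,
                        with_metadata_pcs=mode, n_comparisons=N_COMPARISONS,
                    )
                    res.results.to_csv(
                        outdir / f"categories_{cmp_name}_{tag}.tsv",
                        sep="\t", index=False,
                    )
                    lambda_rows.append(
                        (cmp_name, "category_scan", tag, res.lambda_gc)
                    )
                    stage(f"category_scan:{cmp_name}:{tag}")
                if "window_scan" in plan.analyses:
                    grid = build_window_grid(chrom_lengths, plan.window_sizes_kb)
                    res = window_scan(
                        variants, annotation, samples, comparison, grid, design,
                        n_perm=plan.n_perm, seed=plan.seed,
                        with_metadata_pcs=mode,
                    )
                    res.windows.to_csv(
                        outdir / f"windows_{cmp_name}_{tag}.tsv",
                        sep="\t", index=False,
                    )
                    lambda_rows.append((cmp_name, "window_scan", tag, res.lambda_gc))
                    stage(f"window_scan:{cmp_name}:{tag}")
                if "single_variant" in plan.analyses and not mode:
                    res = single_variant_scan(
                        variants, samples, comparison, base_cov,
                        mac_min=plan.mac_min, annotation=annotation,
                    )
                    res.results.to_csv(
                        outdir / f"variants_{cmp_name}.tsv", sep="\t", index=False
                    )
                    lambda_rows.append(
                        (cmp_name, "single_variant", "base", res.lambda_gc)
                    )
                    stage(f"single_variant:{cmp_name}")
            except Exception as err:
                raise RuntimeError(
                    f"stage failed: {cmp_name}/{tag}: {err}"
                ) from err

    if "ptv" in plan.analyses and consequences is not None:
        unrelated = samples.df.index[samples.df.get("unrelated", True)].tolist()
        catalog = build_ptv_catalog(variants, consequences, unrelated)
        rows = []
        for gene in catalog.tested_genes():
            r = gene_burden_test(catalog, gene, samples)
            rows.append(dataclasses.asdict(r))
        pd.DataFrame(rows).to_csv(outdir / "ptv_genes.tsv", sep="\t", index=False)
        if rows:
            lambda_rows.append(
                ("sz_bd_vs_controls_all", "ptv_gene", "base",
                 float(np.nan) if not rows else _lambda_or_nan([r["p"] for r in rows]))
            )
        set_rows = []
        for name, genes in plan.gene_sets.items():
            r = geneset_burden_test(catalog, list(genes), samples, set_name=name)
            set_rows.append(dataclasses.asdict(r))
        pd.DataFrame(set_rows).to_csv(
            outdir / "ptv_gene_sets.tsv", sep="\t", index=False
        )
        stage("ptv")

    lam = pd.DataFrame(
        lambda_rows, columns=["comparison", "analysis", "mode", "lambda_gc"]
    )
    lam.to_csv(outdir / "lambda_gc_summary.tsv", sep="\t", index=False)
    save_manifest()
    return outdir


def _lambda_or_nan(pvals):
    from .burden import lambda_gc

    p = [x for x in pvals if np.isfinite(x)]
    return lambda_gc(p) if p else float("nan")


def sensitivity_report(
    base: pd.DataFrame,
    with_mpcs: pd.DataFrame,
    unit_columns: Sequence[str],
    threshold: float,
) -> pd.DataFrame:
    """Pair per-unit p-values across covariate modes and flag discordance.

    A unit (state, window, variant) is discordant when it is significant
    at ``threshold`` in exactly one mode — the diagnostic that caught the
    metadata-PC-induced window association in the emulated study.
    """
    b = base.set_index(list(unit_columns))
    m = with_mpcs.set_index(list(unit_columns))
    if not b.index.equals(m.index):
        only_b = b.index.difference(m.index).tolist()[:5]
        only_m = m.index.difference(b.index).tolist()[:5]
        raise ValueError(
            f"unit sets differ between modes; only-base={only_b}, only-mpc={only_m}"
        )
    out = pd.DataFrame(
        {
            "p_base": b["p"],
            "p_mpc": m["p"],
        }
    )
    out["significant_base"] = out["p_base"] < threshold
    out["significant_mpc"] = out["p_mpc"] < threshold
    out["discordant"] = out["significant_base"] != out["significant_mpc"]
    return out.reset_index()
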