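"""Synthetic two-study WGS case-control cohort generator.

Emulates the data structure of a jointly called psychiatric case-control
study combined with deeper-sequenced external controls: a rare-variant
dominated site-frequency spectrum, chromatin/conservation-state and
repeat annotation tracks, per-sample sequencing QC metrics, and — the
key technical feature — excess non-reference calls concentrated in
chosen repeat categories whose per-sample intensity rises smoothly with
sequencing depth.  Because the external study is sequenced ~10x deeper,
the artifact load differs between studies, and because the intensity is
a function of depth, covariates built from sequencing metrics can absorb
it.  True association signals (burden-enriched or -depleted windows,
gene-set PTV enrichment) can be implanted on a liability scale.

All randomness flows from one seed; independent streams are spawned per
component so that, e.g., regenerating with a different artifact rate
leaves genotypes untouched.
"""

from __future__ import annotations

import dataclasses
import json
import hashlib
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .annotation import AnnotationAtlas, annotate_variants
from .cohort import MISSING, SampleFrame, VariantTable

__all__ = [
    "SimConfig",
    "SignalWindow",
    "SyntheticCohort",
    "SyntheticOutputs",
    "simulate_cohort",
    "write_fixture_suite",
    "DEFAULT_FIXTURE_CONFIG",
]

STATE_SYSTEMS = ("chrom_state", "cons_state")

#: repeat categories with genome fraction and typical element length (bp);
#: fractions loosely follow the human RepeatMasker/TRF landscape, with the
#: SINE and simple-repeat shares matching the variant-overlap proportions
#: the downstream tests care about (~16% and ~1%).
REPEAT_LANDSCAPE = {
    "LINE": (0.20, 3000),
    "SINE": (0.16, 300),
    "LTR": (0.08, 1000),
    "DNA": (0.03, 500),
    "Simple_repeat": (0.012, 120),
    "Low_complexity": (0.010, 120),
    "Satellite": (0.005, 2000),
    "DNA?": (0.003, 300),
}

PTV_CONSEQUENCES = ("frameshift", "stop_gained", "splice_acceptor", "splice_donor")


@dataclasses.dataclass(frozen=True)
class SignalWindow:
    """A genomic window whose weighted burden shifts disease log-odds by
    ``effect`` per weighted-burden unit (negative = protective)."""

    chrom: str
    start: int  # 0-based half-open
    end: int
    effect: float

    def as_tuple(self):
        return (self.chrom, self.start, self.end, self.effect)


@dataclasses.dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Sample-group sizes are a ~1/5.6 scale-down of the emulated study
    (1,598 BD / 3,295 SZ / 2,651 internal controls / 14,812 external
    controls) keeping the external controls the largest group; depth
    means and SDs are the two studies' reported sequencing depths.
    """

    n_cases_bd: int = 300
    n_cases_sz: int = 600
    n_controls_internal: int = 500
    n_controls_external: int = 2600
    genome_length_bp: int = 1_000_000
    n_chromosomes: int = 2
    n_variants: int = 40_000
    maf_spectrum: Tuple[float, float] = (0.2, 2.0)  # Beta shape, truncated
    depth_mean_by_study: Dict[str, float] = dataclasses.field(
        default_factory=lambda: {"internal": 26.8, "external": 36.8}
    )
    depth_sd_by_study: Dict[str, float] = dataclasses.field(
        default_factory=lambda: {"internal": 5.5, "external": 4.7}
    )
    artifact_rate_by_category: Dict[str, float] = dataclasses.field(
        default_factory=dict
    )
    #: "quality_modulated": every sample's artifact intensity is
    #: rate * softplus(quality), quality a fixed transform of depth —
    #: the mechanism that lets depth-derived covariates absorb it.
    #: "study_specific": artifacts restricted to artifact_study samples.
    artifact_mode: str = "quality_modulated"
    artifact_study: str = "external"
    indel_fraction: float = 0.03
    gene_pitch_bp: int = 15_000
    gene_coding_bp: int = 3_000
    ptv_fraction_coding: float = 0.30
    signal_windows: Sequence[SignalWindow] = dataclasses.field(default_factory=list)
    signal_geneset: Optional[Tuple[Sequence[str], float]] = None
    seed: int = 0

    def __post_init__(self):
        for name in (
            "n_cases_bd",
            "n_cases_sz",
            "n_controls_internal",
            "n_controls_external",
            "genome_length_bp",
            "n_chromosomes",
            "n_variants",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for cat, rate in self.artifact_rate_by_category.items():
            if not (0 <= rate <= 1):
                raise ValueError(f"artifact rate for {cat!r} outside [0, 1]")
            if cat not in REPEAT_LANDSCAPE:
                raise ValueError(
                    f"artifact category {cat!r} not in the generated repeat "
                    f"landscape {sorted(REPEAT_LANDSCAPE)}"
                )
        if self.artifact_mode not in ("quality_modulated", "study_specific"):
            raise ValueError(f"unknown artifact_mode {self.artifact_mode!r}")
        # canonical container types so configs round-trip through JSON
        self.maf_spectrum = tuple(self.maf_spectrum)
        self.signal_windows = tuple(self.signal_windows)
        if self.signal_geneset is not None:
            genes, orr = self.signal_geneset
            self.signal_geneset = (tuple(genes), float(orr))

    @property
    def n_samples(self) -> int:
        return (
            self.n_cases_bd
            + self.n_cases_sz
            + self.n_controls_internal
            + self.n_controls_external
        )

    @property
    def n_internal(self) -> int:
        return self.n_cases_bd + self.n_cases_sz + self.n_controls_internal

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["signal_windows"] = [w.as_tuple() for w in self.signal_windows]
        d["maf_spectrum"] = list(self.maf_spectrum)
        if self.signal_geneset is not None:
            genes, orr = self.signal_geneset
            d["signal_geneset"] = [list(genes), orr]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        d["signal_windows"] = [SignalWindow(*w) for w in d.get("signal_windows", [])]
        sg = d.get("signal_geneset")
        if sg is not None:
            d["signal_geneset"] = (list(sg[0]), float(sg[1]))
        d["maf_spectrum"] = tuple(d["maf_spectrum"])
        return cls(**d)


@dataclasses.dataclass
class SyntheticOutputs:
    """File paths of a written fixture set."""

    vcf_path: Path
    sample_tsv_path: Path
    state_bed_paths: Dict[str, Path]
    repeat_bed_path: Path
    excluded_bed_path: Path
    consequence_tsv_path: Path
    truth_json_path: Path


def _softplus(x):
    return np.logaddexp(0.0, x)


def _quality(depth):
    """Latent calling-quality score: a fixed affine transform of depth."""
    return (np.asarray(depth, dtype=np.float64) - 30.0) / 5.0


class SyntheticCohort:
    """In-memory simulated cohort: genotypes, samples, tracks, truth."""

    def __init__(self, config, variant_table, samples, atlas, consequences, truth):
        self.config: SimConfig = config
        self.variant_table: VariantTable = variant_table
        self.samples: SampleFrame = samples
        self.atlas: AnnotationAtlas = atlas
        self.consequences: pd.DataFrame = consequences
        self.truth: dict = truth

    def annotate(self):
        return annotate_variants(self.variant_table, self.atlas)

    # ------------------------------------------------------------------
    # writers
    # ------------------------------------------------------------------

    def write(self, outdir) -> SyntheticOutputs:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        vcf = outdir / "cohort.vcf"
        self._write_vcf(vcf)
        sample_tsv = outdir / "samples.tsv"
        self.samples.write_tsv(sample_tsv)
        state_paths = {}
        for system in STATE_SYSTEMS:
            p = outdir / f"{system}.bed"
            self._write_bed(system, p)
            state_paths[system] = p
        repeat_bed = outdir / "repeat.bed"
        self._write_bed("repeat", repeat_bed)
        excluded_bed = outdir / "excluded.bed"
        self._write_bed("excluded", excluded_bed)
        cons_tsv = outdir / "consequences.tsv"
        self.consequences.to_csv(cons_tsv, sep="\t", index=False)
        truth_json = outdir / "truth.json"
        with open(truth_json, "w") as fh:
            json.dump(self.truth, fh, indent=1, sort_keys=True)
        return SyntheticOutputs(
            vcf_path=vcf,
            sample_tsv_path=sample_tsv,
            state_bed_paths=state_paths,
            repeat_bed_path=repeat_bed,
            excluded_bed_path=excluded_bed,
            consequence_tsv_path=cons_tsv,
            truth_json_path=truth_json,
        )

    def _write_bed(self, system: str, path: Path) -> None:
        self.atlas.systems[system].to_csv(
            path, sep="\t", index=False, header=False,
            columns=["chrom", "start", "end", "label"],
        )

    def _write_vcf(self, path: Path) -> None:
        vt = self.variant_table
        gt_codes = np.array(["0/0", "0/1", "1/1", "./."], dtype="U3")
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            for chrom, length in self.truth["chrom_lengths"].items():
                fh.write(f"##contig=<ID={chrom},length={length}>\n")
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(map(str, vt.sample_ids))
                + "\n"
            )
            geno = vt.genotypes
            vdf = self.variant_table.variants
            codes = np.where(geno == MISSING, 3, geno).astype(np.intp)
            for j in range(vt.n_variants):
                row = vdf.iloc[j]
                gts = "\t".join(gt_codes[codes[:, j]].tolist())
                fh.write(
                    f"{row.chrom}\t{row.pos}\t{row.variant_id}\t{row.ref}\t"
                    f"{row.alt}\t.\tPASS\t.\tGT\t{gts}\n"
                )


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def _spawn_rngs(seed: int, names):
    seqs = np.random.SeedSequence(seed).spawn(len(names))
    return {name: np.random.default_rng(s) for name, s in zip(names, seqs)}


#: repeat-affinity of the state labels: genome states are far from
#: independent of repeat content (SINEs and simple repeats concentrate in
#: specific chromatin/conservation states), and that heterogeneity is what
#: makes state-level burden tests sensitive to repeat-specific calling
#: artifacts.  Segments whose midpoint falls in a repeat category draw
#: their state label preferentially from that category's state block.
STATE_AFFINITY_BLOCKS = {
    "SINE": (1, 25),
    "LINE": (26, 50),
    "LTR": (51, 60),
    "DNA": (51, 60),
    "Simple_repeat": (61, 70),
    "Low_complexity": (61, 70),
    "Satellite": (61, 70),
    "DNA?": (51, 60),
    None: (71, 100),
}
STATE_AFFINITY_PROB = {None: 0.5}  # default 0.75 for repeat categories


def _point_category(repeat_df, chrom, points):
    """Repeat category label at each 0-based point (first match), or None."""
    sub = repeat_df[repeat_df["chrom"] == chrom]
    out = np.full(points.shape, None, dtype=object)
    for label, grp in sub.groupby("label"):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        j = np.searchsorted(starts, points, side="right") - 1
        hit = (j >= 0) & (points < ends[np.clip(j, 0, None)]) & (out == None)  # noqa: E711
        out[hit] = label
    return out


def _make_state_track(
    rng, chroms, length, prefix, repeat_df, n_states=100, mean_seg=2000
):
    rows = []
    for chrom in chroms:
        starts = []
        pos = 0
        while pos < length:
            seg = int(rng.geometric(1.0 / mean_seg))
            end = min(pos + max(seg, 50), length)
            starts.append((pos, end))
            pos = end
        seg_arr = np.array(starts)
        mids = (seg_arr[:, 0] + seg_arr[:, 1]) // 2
        cats = _point_category(repeat_df, chrom, mids)
        for (s, e), cat in zip(starts, cats):
            lo, hi = STATE_AFFINITY_BLOCKS.get(cat, STATE_AFFINITY_BLOCKS[None])
            p_affine = STATE_AFFINITY_PROB.get(cat, 0.75)
            if rng.random() < p_affine:
                idx = rng.integers(lo, hi + 1)
            else:
                idx = rng.integers(1, n_states + 1)
            rows.append((chrom, s, e, f"{prefix}{idx}"))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "label"])


def _make_repeat_track(rng, chroms, length):
    rows = []
    for chrom in chroms:
        for label, (fraction, elem_len) in REPEAT_LANDSCAPE.items():
            n_elem = int(round(fraction * length / elem_len))
            starts = rng.integers(0, max(length - elem_len, 1), size=n_elem)
            for s in np.sort(starts):
                rows.append((chrom, int(s), int(min(s + elem_len, length)), label))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "label"])
    return df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(
        drop=True
    )


def _make_excluded_track(rng, chroms, length, fraction=0.01, elem_len=5000):
    rows = []
    for chrom in chroms:
        n_elem = int(round(fraction * length / elem_len))
        starts = np.sort(rng.integers(0, max(length - elem_len, 1), size=n_elem))
        for s in starts:
            rows.append((chrom, int(s), int(min(s + elem_len, length)), "excluded"))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "label"])


def _truncated_beta(rng, a, b, lo, hi, size):
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.beta(a, b, size=size - filled)
        keep = draw[(draw > lo) & (draw < hi)]
        out[filled : filled + keep.size] = keep
        filled += keep.size
    return out


def simulate_cohort(config: SimConfig, outdir=None):
    """Generate a cohort under ``config``.

    Returns the in-memory :class:`SyntheticCohort`; if ``outdir`` is
    given the fixture files are also written and the cohort's
    ``outputs`` attribute holds the :class:`SyntheticOutputs`.
    """
    rngs = _spawn_rngs(
        config.seed,
        [
            "tracks",
            "positions",
            "mafs",
            "alleles",
            "genotypes",
            "artifact",
            "metrics",
            "phenotype",
            "covariates",
        ],
    )
    chroms = [f"chr{i+1}" for i in range(config.n_chromosomes)]
    L = config.genome_length_bp
    chrom_lengths = {c: L for c in chroms}

    atlas = AnnotationAtlas()
    repeat_df = _make_repeat_track(rngs["tracks"], chroms, L)
    atlas.add("repeat", repeat_df)
    atlas.add(
        "chrom_state", _make_state_track(rngs["tracks"], chroms, L, "chrom_", repeat_df)
    )
    atlas.add(
        "cons_state", _make_state_track(rngs["tracks"], chroms, L, "cons_", repeat_df)
    )
    atlas.add("excluded", _make_excluded_track(rngs["tracks"], chroms, L))

    # -- variant sites ----------------------------------------------------
    n_per_chrom = np.full(len(chroms), config.n_variants // len(chroms))
    n_per_chrom[: config.n_variants % len(chroms)] += 1
    chrom_col, pos_col = [], []
    for c, n_c in zip(chroms, n_per_chrom):
        pos = np.sort(rngs["positions"].choice(L, size=n_c, replace=False)) + 1
        chrom_col.append(np.full(n_c, c, dtype=object))
        pos_col.append(pos)
    chrom_col = np.concatenate(chrom_col)
    pos_col = np.concatenate(pos_col)
    m = config.n_variants

    n2 = 2 * config.n_samples
    a, b = config.maf_spectrum
    maf_true = _truncated_beta(rngs["mafs"], a, b, 1.0 / n2, 0.5, m)

    bases = np.array(list("ACGT"))
    ref_idx = rngs["alleles"].integers(0, 4, size=m)
    alt_shift = rngs["alleles"].integers(1, 4, size=m)
    ref = bases[ref_idx]
    alt = bases[(ref_idx + alt_shift) % 4]
    is_indel = rngs["alleles"].random(m) < config.indel_fraction
    alt = np.where(is_indel, np.char.add(alt, ref), alt)
    variant_id = np.array(
        [f"{c}:{p}:{r}:{al}" for c, p, r, al in zip(chrom_col, pos_col, ref, alt)],
        dtype=object,
    )
    vdf = pd.DataFrame(
        {
            "variant_id": variant_id,
            "chrom": chrom_col,
            "pos": pos_col,
            "ref": ref,
            "alt": alt,
            "is_snv": ~is_indel,
        }
    )

    # -- genotypes (chunked to keep the transient int64 buffer small) ----
    n = config.n_samples
    geno = np.empty((n, m), dtype=np.int8)
    chunk = max(1, 2_000_000 // max(n, 1))
    for j0 in range(0, m, chunk):
        j1 = min(j0 + chunk, m)
        geno[:, j0:j1] = rngs["genotypes"].binomial(
            2, maf_true[j0:j1], size=(n, j1 - j0)
        )

    # -- samples, depths, metrics ----------------------------------------
    study = np.array(
        ["internal"] * config.n_internal + ["external"] * config.n_controls_external,
        dtype=object,
    )
    depth = np.empty(n)
    for s in ("internal", "external"):
        mask = study == s
        depth[mask] = rngs["metrics"].normal(
            config.depth_mean_by_study[s], config.depth_sd_by_study[s], mask.sum()
        )
    quality = _quality(depth)
    mr = rngs["metrics"]
    metrics = pd.DataFrame(
        {
            "depth_mean": depth,
            "contamination": np.clip(
                0.004 + 0.0015 * quality + 0.002 * mr.normal(size=n), 0, None
            ),
            "insert_size": 400.0 + 6.0 * quality + 8.0 * mr.normal(size=n),
            "base_quality": 35.0 + 0.8 * quality + 0.7 * mr.normal(size=n),
            "gc_dropout": np.clip(
                1.0 - 0.15 * quality + 0.25 * mr.normal(size=n), 0, None
            ),
        }
    )

    # -- differential-calling artifacts ----------------------------------
    annotation = annotate_variants(
        VariantTable(variants=vdf, genotypes=geno[:1].copy(), sample_ids=["_probe"]),
        atlas,
    )
    artifact_counts = np.zeros(n, dtype=np.int64)
    artifact_variants: Dict[str, List[str]] = {}
    if config.artifact_rate_by_category:
        if config.artifact_mode == "quality_modulated":
            intensity = _softplus(quality)
        else:
            intensity = _softplus(quality) * (study == config.artifact_study)
        for cat, rate in config.artifact_rate_by_category.items():
            members = annotation.members("repeat", cat)
            if members.size == 0:
                continue
            artifact_variants[cat] = vdf["variant_id"].to_numpy()[members].tolist()
            p_sample = np.clip(rate * intensity, 0.0, 1.0)
            flips = rngs["artifact"].random((n, members.size)) < p_sample[:, None]
            artifact_counts += flips.sum(axis=1)
            sub = geno[:, members]
            geno[:, members] = np.minimum(sub + flips.astype(np.int8), 2)

    # -- gene map and consequences ---------------------------------------
    gene_rows = []
    g_id = 0
    for c in chroms:
        for start in range(0, L - config.gene_pitch_bp + 1, config.gene_pitch_bp):
            g_id += 1
            gene_rows.append((f"GENE{g_id:04d}", c, start, start + config.gene_coding_bp))
    genes = pd.DataFrame(gene_rows, columns=["gene_id", "chrom", "start", "end"])
    cons_label = np.full(m, "other", dtype=object)
    gene_of = np.full(m, "", dtype=object)
    for _, g in genes.iterrows():
        in_gene = (
            (chrom_col == g.chrom) & (pos_col - 1 >= g.start) & (pos_col - 1 < g.end)
        )
        gene_of[in_gene] = g.gene_id
    coding = gene_of != ""
    is_ptv = coding & (rngs["covariates"].random(m) < config.ptv_fraction_coding)
    cons_label[is_ptv] = rngs["covariates"].choice(PTV_CONSEQUENCES, size=int(is_ptv.sum()))
    consequences = pd.DataFrame(
        {
            "variant_id": vdf["variant_id"],
            "gene_id": np.where(coding, gene_of, "."),
            "consequence": cons_label,
        }
    )

    # -- phenotype: liability with implanted signals ---------------------
    from .burden import WeightScheme, variant_weight

    weights = np.zeros(m)
    wmask = (maf_true < 0.05) & (~is_indel)
    weights[wmask] = variant_weight(maf_true[wmask], WeightScheme())

    eta = np.zeros(n)
    for w in config.signal_windows:
        in_w = (chrom_col == w.chrom) & (pos_col - 1 >= w.start) & (pos_col - 1 < w.end)
        widx = np.where(in_w & wmask)[0]
        if widx.size == 0:
            raise ValueError(
                f"signal window {w.chrom}:{w.start}-{w.end} contains no "
                "weightable variants; enlarge the window or n_variants"
            )
        eta += w.effect * (geno[:, widx].astype(np.float64) @ weights[widx])
    geneset_ptv_counts = None
    if config.signal_geneset is not None:
        gset, or_set = config.signal_geneset
        ac = np.where(geno == MISSING, 0, geno).sum(axis=0)
        singleton = ac == 1
        in_set = np.isin(gene_of, list(gset)) & is_ptv & singleton
        geneset_ptv_counts = (
            np.where(geno[:, in_set] == MISSING, 0, geno[:, in_set])
            .astype(np.float64)
            .sum(axis=1)
        )
        eta += np.log(or_set) * geneset_ptv_counts

    n_cases = config.n_cases_bd + config.n_cases_sz
    internal_idx = np.where(study == "internal")[0]
    liability = eta[internal_idx] + rngs["phenotype"].logistic(size=internal_idx.size)
    case_rows = internal_idx[np.argsort(liability)[::-1][:n_cases]]
    phen = np.full(n, "CONTROL", dtype=object)
    case_perm = rngs["phenotype"].permutation(case_rows)
    phen[case_perm[: config.n_cases_bd]] = "BD"
    phen[case_perm[config.n_cases_bd :]] = "SZ"

    sample_ids = np.array(
        [f"INP{i+1:05d}" for i in range(config.n_internal)]
        + [f"EXT{i+1:05d}" for i in range(config.n_controls_external)],
        dtype=object,
    )
    cov_rng = rngs["covariates"]
    sdf = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "study": study,
            "phenotype": phen,
            "sex": cov_rng.choice([1, 2], size=n),
            "batch": np.where(
                study == "internal",
                np.char.add("batch", cov_rng.integers(1, 8, n).astype(str)),
                np.char.add("center", cov_rng.integers(1, 6, n).astype(str)),
            ),
            "unrelated": True,
        }
    )
    for i in range(1, 11):
        sdf[f"pc{i}"] = cov_rng.normal(size=n)
    for col in metrics.columns:
        sdf[col] = metrics[col].to_numpy()
    samples = SampleFrame(sdf)

    truth = {
        "config": config.to_dict(),
        "chrom_lengths": chrom_lengths,
        "signal_windows": [w.as_tuple() for w in config.signal_windows],
        "signal_geneset": (
            None
            if config.signal_geneset is None
            else [list(config.signal_geneset[0]), config.signal_geneset[1]]
        ),
        "artifact_rate_by_category": dict(config.artifact_rate_by_category),
        "artifact_mode": config.artifact_mode,
        "n_artifact_alleles_total": int(artifact_counts.sum()),
        "artifact_variants": artifact_variants,
    }

    cohort = SyntheticCohort(
        config=config,
        variant_table=VariantTable(variants=vdf, genotypes=geno, sample_ids=sample_ids),
        samples=samples,
        atlas=atlas,
        consequences=consequences,
        truth=truth,
    )
    cohort.latent_quality = quality
    cohort.artifact_counts = artifact_counts
    cohort.maf_true = maf_true
    if geneset_ptv_counts is not None:
        cohort.geneset_ptv_counts = geneset_ptv_counts
    if outdir is not None:
        cohort.outputs = cohort.write(outdir)
    return cohort


#: canonical fixture conditions: one protective window on chr1 and a
#: depth-modulated excess-call artifact in the SINE category.  The rate
#: is set so the SINE enrichment is decisively detectable at fixture
#: scale (per-state artifact shifts of a few null SDs), mirroring the
#: overwhelming significance of the differential SINE calling the
#: emulated study observed.
DEFAULT_FIXTURE_CONFIG = SimConfig(
    artifact_rate_by_category={"SINE": 0.005},
    signal_windows=[SignalWindow("chr1", 200_000, 210_000, -0.02)],
    signal_geneset=(tuple(f"GENE{i:04d}" for i in range(1, 26)), 1.5),
    seed=20_240_101,
)


def write_fixture_suite(outdir, config: SimConfig = DEFAULT_FIXTURE_CONFIG):
    """Write the canonical fixture set used across module tests."""
    cohort = simulate_cohort(config, outdir=outdir)
    return cohort.outputs


def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()
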