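"""Interval annotation tracks and per-variant category assignment.

Four annotation systems drive the scans: two genome partitions into
chromatin and conservation states (each variant belongs to exactly one
state), a repeat track whose categories may overlap (RepeatMasker-style),
and an excluded-regions blacklist.  BED inputs are 0-based half-open; VCF
variant positions are 1-based, so a variant at position ``p`` is assigned
the interval containing ``p - 1``.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "AnnotationAtlas",
    "VariantAnnotationSet",
    "load_bed_track",
    "annotate_variants",
    "repeat_category_table",
    "ANY_REPEAT",
    "UNASSIGNED",
]

logger = logging.getLogger(__name__)

UNASSIGNED = "unassigned"
ANY_REPEAT = "any_repeat"

#: systems treated as genome partitions (overlapping intervals are an input error)
PARTITION_SYSTEMS = ("chrom_state", "cons_state")


@dataclasses.dataclass
class AnnotationAtlas:
    """Interval indexes per annotation system.

    ``systems`` maps a system name ("chrom_state", "cons_state", "repeat",
    "excluded") to a normalised interval table (chrom, start, end, label);
    ``label_universe`` holds the ordered label list per system.
    """

    systems: Dict[str, pd.DataFrame] = dataclasses.field(default_factory=dict)
    label_universe: Dict[str, List[str]] = dataclasses.field(default_factory=dict)

    def add(self, system: str, intervals: pd.DataFrame) -> None:
        self.systems[system] = intervals.reset_index(drop=True)
        self.label_universe[system] = sorted(intervals["label"].unique().tolist())

    def chromosomes(self, system: str):
        return set(self.systems[system]["chrom"].unique())


def load_bed_track(
    path,
    system: str,
    atlas: Optional[AnnotationAtlas] = None,
    overlap_policy: Optional[str] = None,
) -> AnnotationAtlas:
    """Parse a BED4+ file into an atlas entry.

    ``overlap_policy`` is "error" (reject overlapping intervals, the
    default for state partitions) or "allow" (repeats legitimately
    overlap).  Malformed lines are rejected with their line number.
    """
    if overlap_policy is None:
        overlap_policy = "error" if system in PARTITION_SYSTEMS else "allow"
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(
                    f"{path}:{lineno}: expected >=4 tab-separated BED columns"
                )
            chrom, start_s, end_s, label = parts[0], parts[1], parts[2], parts[3]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from None
            if end <= start:
                raise ValueError(
                    f"{path}:{lineno}: end ({end}) must exceed start ({start})"
                )
            rows.append((chrom, start, end, label))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "label"])
    df = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(
        drop=True
    )
    if overlap_policy == "error":
        prev_end = df.groupby("chrom")["end"].cummax().shift()
        same_chrom = df["chrom"] == df["chrom"].shift()
        clash = same_chrom & (df["start"] < prev_end)
        if clash.any():
            i = int(np.where(clash)[0][0])
            a, b = df.iloc[i - 1], df.iloc[i]
            raise ValueError(
                f"overlapping intervals in {system}: "
                f"{a.chrom}:{a.start}-{a.end}({a.label}) and "
                f"{b.chrom}:{b.start}-{b.end}({b.label})"
            )
    elif overlap_policy != "allow":
        raise ValueError(f"unknown overlap policy {overlap_policy!r}")
    atlas = atlas if atlas is not None else AnnotationAtlas()
    atlas.add(system, df)
    return atlas


@dataclasses.dataclass
class VariantAnnotationSet:
    """Per-variant category assignments across all loaded systems.

    ``labels`` covers partition systems (one label or "unassigned" per
    variant); ``repeat_members`` maps each repeat category (plus the
    "any_repeat" union) to the variant indices it contains — a variant in
    several overlapping repeat categories appears once per category and
    once in the union.
    """

    labels: Dict[str, np.ndarray]
    repeat_members: Dict[str, np.ndarray]
    excluded: Optional[np.ndarray]
    label_universe: Dict[str, List[str]]
    variant_ids: np.ndarray

    def members(self, system: str, label: str) -> np.ndarray:
        """Indices of variants carrying ``label`` in ``system``."""
        if system == "repeat":
            return self.repeat_members.get(label, np.empty(0, dtype=np.intp))
        return np.where(self.labels[system] == label)[0]


def _partition_lookup(intervals: pd.DataFrame, chrom: str, pos0: np.ndarray):
    """Label indices for 0-based positions against non-overlapping sorted
    intervals of one chromosome; -1 where uncovered."""
    sub = intervals[intervals["chrom"] == chrom]
    starts = sub["start"].to_numpy()
    ends = sub["end"].to_numpy()
    j = np.searchsorted(starts, pos0, side="right") - 1
    ok = (j >= 0) & (pos0 < ends[np.clip(j, 0, None)])
    out = np.where(ok, j, -1)
    return out, sub


def annotate_variants(variants, atlas: AnnotationAtlas) -> VariantAnnotationSet:
    """Assign each variant its state labels, repeat categories and
    excluded-region flag.

    Variants on chromosomes absent from a track get "unassigned" (with a
    logged warning), not an error.  Indels are annotated by their VCF
    anchor position.
    """
    vdf = variants.variants
    pos0_all = vdf["pos"].to_numpy(dtype=np.int64) - 1
    chroms = vdf["chrom"].to_numpy()
    n = len(vdf)

    labels: Dict[str, np.ndarray] = {}
    for system in atlas.systems:
        if system in ("repeat", "excluded"):
            continue
        lab = np.full(n, UNASSIGNED, dtype=object)
        track_chroms = atlas.chromosomes(system)
        for chrom in pd.unique(chroms):
            vidx = np.where(chroms == chrom)[0]
            if chrom not in track_chroms:
                logger.warning(
                    "chromosome %s absent from %s track; %d variants unassigned",
                    chrom,
                    system,
                    vidx.size,
                )
                continue
            j, sub = _partition_lookup(atlas.systems[system], chrom, pos0_all[vidx])
            hit = j >= 0
            lab[vidx[hit]] = sub["label"].to_numpy()[j[hit]]
        labels[system] = lab

    repeat_members: Dict[str, List[int]] = {}
    if "repeat" in atlas.systems:
        trees: Dict[str, IntervalTree] = {}
        for chrom, grp in atlas.systems["repeat"].groupby("chrom"):
            trees[chrom] = IntervalTree.from_tuples(
                zip(grp["start"], grp["end"], grp["label"])
            )
        per_label: Dict[str, List[int]] = {
            lab: [] for lab in atlas.label_universe["repeat"]
        }
        union: List[int] = []
        for chrom in pd.unique(chroms):
            tree = trees.get(chrom)
            vidx = np.where(chroms == chrom)[0]
            if tree is None:
                logger.warning(
                    "chromosome %s absent from repeat track; %d variants outside repeats",
                    chrom,
                    vidx.size,
                )
                continue
            for i in vidx:
                hits = tree[pos0_all[i]]
                if hits:
                    union.append(i)
                    for h in {h.data for h in hits}:
                        per_label[h].append(i)
        repeat_members = {
            lab: np.array(sorted(ix), dtype=np.intp) for lab, ix in per_label.items()
        }
        repeat_members[ANY_REPEAT] = np.array(sorted(union), dtype=np.intp)

    excluded = None
    if "excluded" in atlas.systems:
        excluded = np.zeros(n, dtype=bool)
        ex = atlas.systems["excluded"]
        for chrom, grp in ex.groupby("chrom"):
            vidx = np.where(chroms == chrom)[0]
            if vidx.size == 0:
                continue
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            # excluded intervals may overlap; merge on the fly
            order = np.argsort(starts)
            starts, ends = starts[order], ends[order]
            merged_s, merged_e = [], []
            for s, e in zip(starts, ends):
                if merged_e and s <= merged_e[-1]:
                    merged_e[-1] = max(merged_e[-1], e)
                else:
                    merged_s.append(s)
                    merged_e.append(e)
            ms = np.array(merged_s)
            me = np.array(merged_e)
            p = pos0_all[vidx]
            j = np.searchsorted(ms, p, side="right") - 1
            inside = (j >= 0) & (p < me[np.clip(j, 0, None)])
            excluded[vidx[inside]] = True

    universe = dict(atlas.label_universe)
    if "repeat" in universe:
        universe["repeat"] = repeat_category_table(atlas)
    return VariantAnnotationSet(
        labels=labels,
        repeat_members=repeat_members,
        excluded=excluded,
        label_universe=universe,
        variant_ids=vdf["variant_id"].to_numpy(),
    )


def repeat_category_table(atlas: AnnotationAtlas) -> List[str]:
    """Repeat category labels plus the "any_repeat" union category
    (21 labels in, 22 categories out for the RepeatMasker/TRF track)."""
    if "repeat" not in atlas.systems:
        raise KeyError("repeat system not loaded")
    return list(atlas.label_universe["repeat"]) + [ANY_REPEAT]
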