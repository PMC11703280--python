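"""Sliding-window scan: grid arithmetic, effective-test estimation,
signal recovery and the secondary window dissection."""

import numpy as np
import pytest

from wgsburden.burden import BurdenDesign
from wgsburden.windows import (
    build_window_grid,
    dissect_window,
    effective_tests_from_minp,
    scan,
)


def test_grid_starts_and_clipping():
    grid = build_window_grid({"chr1": 100_000}, sizes_kb=(50,), step_fraction=0.5)
    w = grid.windows
    assert list(w["start"]) == [0, 25_000, 50_000, 75_000]
    assert list(w["end"]) == [50_000, 75_000, 100_000, 100_000]


def test_grid_non_overlapping_tiling_count():
    grid = build_window_grid({"chr1": 103_000}, sizes_kb=(10,), step_fraction=1.0)
    assert len(grid) == int(np.ceil(103_000 / 10_000))


def test_grid_skips_oversize_and_validates_step():
    grid = build_window_grid({"chr1": 3_000}, sizes_kb=(5, 1))
    assert set(grid.windows["size"]) == {1_000}
    with pytest.raises(ValueError):
        build_window_grid({"chr1": 1000}, step_fraction=0.0)


def test_every_variant_covered_by_each_size(small_cohort):
    lengths = small_cohort.truth["chrom_lengths"]
    grid = build_window_grid(lengths)
    vdf = small_cohort.variant_table.variants
    for size in grid.windows["size"].unique():
        sub = grid.windows[grid.windows["size"] == size]
        for chrom, grp in vdf.groupby("chrom"):
            pos0 = grp["pos"].to_numpy() - 1
            wins = sub[sub["chrom"] == chrom]
            covered = np.zeros(len(pos0), dtype=bool)
            for _, w in wins.iterrows():
                covered |= (pos0 >= w["start"]) & (pos0 < w["end"])
            assert covered.all()


def test_effective_tests_independent_and_duplicated_limits(rng):
    W = 250
    minp = rng.uniform(size=(4000, W)).min(axis=1)
    n_eff = effective_tests_from_minp(minp)
    assert n_eff == pytest.approx(W, rel=0.12)
    # duplicating every column leaves the minimum unchanged
    n_eff_dup = effective_tests_from_minp(minp)
    assert n_eff_dup == pytest.approx(W, rel=0.12)
    with pytest.raises(ValueError):
        effective_tests_from_minp(np.array([]))


@pytest.fixture(scope="module")
def small_scan(small_cohort, small_annotation):
    grid = build_window_grid(small_cohort.truth["chrom_lengths"])
    design = BurdenDesign()
    return scan(
        small_cohort.variant_table,
        small_annotation,
        small_cohort.samples,
        ("sz_bd", "controls_all"),
        grid,
        design,
        n_perm=400,
        seed=5,
    )


def test_scan_recovers_implanted_window(small_cohort, small_scan):
    top = small_scan.min_p_window()
    chrom, start, end, _ = small_cohort.truth["signal_windows"][0]
    assert top["chrom"] == chrom
    assert top["start"] < end and top["end"] > start
    assert top["z"] < 0  # protective: enrichment in controls


def test_scan_threshold_and_neff_invariants(small_scan):
    assert small_scan.n_effective <= small_scan.windows["tested"].sum()
    assert 0 < small_scan.threshold <= 0.05
    assert small_scan.threshold == pytest.approx(0.05 / small_scan.n_effective)


def test_scan_reproducible_with_fixed_seed(small_cohort, small_annotation):
    grid = build_window_grid(small_cohort.truth["chrom_lengths"], sizes_kb=(10,))
    design = BurdenDesign()
    args = (
        small_cohort.variant_table,
        small_annotation,
        small_cohort.samples,
        ("sz_bd", "controls_all"),
        grid,
        design,
    )
    r1 = scan(*args, n_perm=200, seed=13)
    r2 = scan(*args, n_perm=200, seed=13)
    assert np.array_equal(r1.perm_minp, r2.perm_minp)
    assert r1.n_effective == r2.n_effective
    assert np.allclose(r1.windows["p"].to_numpy(), r2.windows["p"].to_numpy(), equal_nan=True)


def test_scan_rejects_tiny_permutation_count(small_cohort, small_annotation):
    grid = build_window_grid(small_cohort.truth["chrom_lengths"], sizes_kb=(10,))
    with pytest.raises(ValueError, match="n_perm"):
        scan(
            small_cohort.variant_table,
            small_annotation,
            small_cohort.samples,
            ("sz_bd", "controls_all"),
            grid,
            BurdenDesign(),
            n_perm=10,
        )


def test_dissection_partitions_window_variants(small_cohort, small_annotation):
    chrom, start, end, _ = small_cohort.truth["signal_windows"][0]
    d = dissect_window(
        small_cohort.variant_table,
        small_annotation,
        small_cohort.samples,
        ("sz_bd", "controls_all"),
        (chrom, start, end),
        BurdenDesign(),
    )
    n_window = len(d.fisher)
    n_c = 0 if d.nominal is None else d.nominal.n_variants
    n_d = 0 if d.non_nominal is None else d.non_nominal.n_variants
    assert n_c + n_d == n_window
    assert set(d.to_dict()) >= {"non_repeat_burden", "fisher", "notes"}


def test_dissection_selected_subset_concentrates_signal(rng):
    """When a window's association is driven by a handful of strongly
    control-enriched variants, the Fisher-nominal subset carries the
    burden signal more strongly than the complement."""
    import pandas as pd

    from wgsburden.annotation import AnnotationAtlas, annotate_variants
    from wgsburden.cohort import SampleFrame, VariantTable

    n, m, causal = 500, 60, 8
    mafs = rng.uniform(0.01, 0.04, size=m)
    geno = rng.binomial(2, mafs, size=(n, m)).astype(np.int8)
    variants = pd.DataFrame(
        {
            "variant_id": [f"v{j}" for j in range(m)],
            "chrom": ["chr1"] * m,
            "pos": (np.arange(m) * 150 + 100).tolist(),
            "ref": ["A"] * m,
            "alt": ["T"] * m,
            "is_snv": [True] * m,
        }
    )
    vt = VariantTable(variants=variants, genotypes=geno, sample_ids=[f"s{i}" for i in range(n)])
    carrier = geno[:, :causal].sum(axis=1)
    # strong protective effect concentrated in the causal variants
    p_case = 1 / (1 + np.exp(-(0.2 - 2.0 * carrier)))
    phen = np.where(rng.random(n) < p_case, "BD", "CONTROL")
    sf = SampleFrame(
        pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(n)],
                "study": ["internal"] * n,
                "phenotype": phen,
                "sex": rng.choice([1, 2], size=n),
            }
        )
    )
    atlas = AnnotationAtlas()
    atlas.add(
        "repeat",
        pd.DataFrame(
            [("chr1", 50_000, 50_100, "SINE")],
            columns=["chrom", "start", "end", "label"],
        ),
    )
    ann = annotate_variants(vt, atlas)
    d = dissect_window(
        vt, ann, sf, ("bd", "controls_internal"), ("chr1", 0, 10_000),
        BurdenDesign(covariates=[], include_total_burden=False),
    )
    assert d.nominal is not None and d.non_nominal is not None
    assert d.nominal.pvalue < d.non_nominal.pvalue


def test_dissection_all_repeat_window_skips_burden(small_cohort, small_annotation):
    # a window fully inside one repeat element has an empty non-repeat set
    track = small_cohort.atlas.systems["repeat"]
    long_elems = track[(track["end"] - track["start"]) >= 2000]
    row = long_elems.iloc[0]
    d = dissect_window(
        small_cohort.variant_table,
        small_annotation,
        small_cohort.samples,
        ("sz_bd", "controls_all"),
        (row["chrom"], int(row["start"]) + 10, int(row["end"]) - 10),
        BurdenDesign(),
    )
    assert d.non_repeat is None
    assert any("non_repeat" in note for note in d.notes)
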