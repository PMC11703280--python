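"""Synthetic cohort generator: determinism, output contracts, spectrum,
artifact containment and signal implantation."""

import dataclasses
import json

import numpy as np
import pytest
from scipy import stats

from wgsburden import SimConfig, SignalWindow, VariantTable, simulate_cohort
from wgsburden.burden import variant_weight
from wgsburden.synthetic import (
    DEFAULT_FIXTURE_CONFIG,
    _truncated_beta,
    file_digest,
    write_fixture_suite,
)

TINY = dataclasses.replace(
    DEFAULT_FIXTURE_CONFIG,
    n_cases_bd=15,
    n_cases_sz=25,
    n_controls_internal=30,
    n_controls_external=80,
    n_chromosomes=2,
    genome_length_bp=120_000,
    n_variants=1_500,
    artifact_rate_by_category={"SINE": 0.01},
    signal_windows=(SignalWindow("chr1", 30_000, 45_000, -0.05),),
    signal_geneset=(("GENE0001", "GENE0002"), 1.5),
    seed=99,
)


def test_config_validation():
    with pytest.raises(ValueError, match="positive"):
        SimConfig(n_cases_bd=0)
    with pytest.raises(ValueError, match="outside"):
        SimConfig(artifact_rate_by_category={"SINE": 1.5})
    with pytest.raises(ValueError, match="not in the generated repeat"):
        SimConfig(artifact_rate_by_category={"ALU-ish": 0.01})
    with pytest.raises(ValueError, match="artifact_mode"):
        SimConfig(artifact_mode="sometimes")


def test_fixture_suite_round_trip(tmp_path):
    out = write_fixture_suite(tmp_path / "fx", TINY)
    vt = VariantTable.from_vcf(out.vcf_path)
    assert vt.n_samples == TINY.n_samples
    assert vt.n_variants == TINY.n_variants
    # bi-allelic, strictly increasing positions within chromosome
    for chrom, grp in vt.variants.groupby("chrom"):
        assert np.all(np.diff(grp["pos"].to_numpy()) > 0)
    truth = json.loads(out.truth_json_path.read_text())
    assert truth["signal_windows"] == [["chr1", 30_000, 45_000, -0.05]]
    assert SimConfig.from_dict(truth["config"]) == TINY


def test_seeded_regeneration_is_byte_identical(tmp_path):
    o1 = write_fixture_suite(tmp_path / "a", TINY)
    o2 = write_fixture_suite(tmp_path / "b", TINY)
    for attr in ("vcf_path", "sample_tsv_path", "consequence_tsv_path", "truth_json_path"):
        assert file_digest(getattr(o1, attr)) == file_digest(getattr(o2, attr))
    for system, p in o1.state_bed_paths.items():
        assert file_digest(p) == file_digest(o2.state_bed_paths[system])


def test_written_genotypes_match_memory(tmp_path):
    cohort = simulate_cohort(TINY, outdir=tmp_path / "x")
    vt = VariantTable.from_vcf(cohort.outputs.vcf_path)
    assert np.array_equal(vt.genotypes, cohort.variant_table.genotypes)


def test_truncated_beta_sampler_matches_analytic_cdf(rng):
    a, b, lo, hi = 0.2, 2.0, 1e-4, 0.5
    draws = _truncated_beta(rng, a, b, lo, hi, 10_000)
    assert draws.min() > lo and draws.max() < hi
    base = stats.beta(a, b)
    norm = base.cdf(hi) - base.cdf(lo)
    cdf = lambda x: (base.cdf(x) - base.cdf(lo)) / norm
    ks = stats.ks_1samp(draws, cdf).statistic
    assert ks < 0.02


def test_observed_maf_tracks_configured_spectrum():
    cfg = dataclasses.replace(
        TINY, n_variants=12_000, genome_length_bp=1_000_000, artifact_rate_by_category={},
        signal_windows=(), signal_geneset=None,
    )
    c = simulate_cohort(cfg)
    # the site frequencies driving the genotypes follow the truncated
    # Beta spectrum (the sampler itself is KS-tested separately) ...
    base = stats.beta(*cfg.maf_spectrum)
    lo, hi = 1 / (2 * cfg.n_samples), 0.5
    norm = base.cdf(hi) - base.cdf(lo)
    ks = stats.ks_1samp(
        c.maf_true, lambda x: (base.cdf(x) - base.cdf(lo)) / norm
    ).statistic
    assert ks < 0.02
    # ... and the empirical per-variant frequency tracks them closely
    aaf = c.variant_table.alt_allele_frequency()
    r = np.corrcoef(aaf, c.maf_true)[0, 1]
    assert r > 0.95
    # the share below the rare/low-frequency cut matches the truncated
    # spectrum's analytic mass
    expected_rare = (base.cdf(0.05) - base.cdf(lo)) / norm
    assert (c.maf_true < 0.05).mean() == pytest.approx(expected_rare, abs=0.02)


def test_artifacts_confined_to_study_and_categories():
    base_cfg = dataclasses.replace(
        TINY, artifact_rate_by_category={}, signal_windows=(), signal_geneset=None
    )
    art_cfg = dataclasses.replace(
        base_cfg,
        artifact_rate_by_category={"SINE": 0.05},
        artifact_mode="study_specific",
    )
    c0 = simulate_cohort(base_cfg)
    c1 = simulate_cohort(art_cfg)
    diff = c0.variant_table.genotypes != c1.variant_table.genotypes
    assert diff.any()
    ext = c1.samples.df["study"].to_numpy() == "external"
    # only external samples touched
    assert not diff[~ext].any()
    # only SINE variants touched
    sine = set(c1.annotate().members("repeat", "SINE"))
    assert set(np.where(diff.any(axis=0))[0]) <= sine


def test_external_controls_carry_higher_sine_burden():
    cfg = dataclasses.replace(TINY, signal_windows=(), signal_geneset=None)
    c = simulate_cohort(cfg)
    ann = c.annotate()
    members = ann.members("repeat", "SINE")
    maf = c.variant_table.maf()
    ok = members[(maf[members] > 0) & (maf[members] < 1)]
    w = variant_weight(np.clip(maf[ok], 1e-9, 1 - 1e-9))
    burden = c.variant_table.dosage()[:, ok] @ w
    study = c.samples.df["study"].to_numpy()
    phen = c.samples.df["phenotype"].to_numpy()
    assert (
        burden[(study == "external")].mean()
        > burden[(study == "internal") & (phen == "CONTROL")].mean()
    )


def test_signal_window_without_variants_is_an_error():
    cfg = dataclasses.replace(
        TINY,
        n_variants=30,
        signal_windows=(SignalWindow("chr2", 100, 140, -0.1),),
        signal_geneset=None,
    )
    with pytest.raises(ValueError, match="chr2:100-140"):
        simulate_cohort(cfg)


def test_group_sizes_match_config():
    c = simulate_cohort(TINY)
    counts = c.samples.df["phenotype"].value_counts()
    assert counts["BD"] == TINY.n_cases_bd
    assert counts["SZ"] == TINY.n_cases_sz
    study = c.samples.df["study"]
    assert (study == "external").sum() == TINY.n_controls_external
    assert c.samples.df.loc[study == "external", "phenotype"].eq("CONTROL").all()


def test_protective_window_lowers_case_burden():
    c = simulate_cohort(TINY)
    w = TINY.signal_windows[0]
    vdf = c.variant_table.variants
    in_w = (
        (vdf["chrom"] == w.chrom)
        & (vdf["pos"] - 1 >= w.start)
        & (vdf["pos"] - 1 < w.end)
    ).to_numpy()
    maf = c.variant_table.maf()
    ok = in_w & (maf > 0) & (maf < 0.05)
    weights = variant_weight(maf[ok])
    burden = c.variant_table.dosage()[:, ok] @ weights
    phen = c.samples.df["phenotype"].to_numpy()
    study = c.samples.df["study"].to_numpy()
    cases = np.isin(phen, ["BD", "SZ"])
    ctrl = (phen == "CONTROL") & (study == "internal")
    assert burden[cases].mean() < burden[ctrl].mean()
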