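"""Synthetic generator: Poisson occupancy, determinism, panels, cohorts."""

import math

import pandas as pd
import pytest

from dropscreen.simulate import (
    ChamberConfig,
    demo_cohort_table,
    parse_mutations,
    simulate_blank_panel,
    simulate_chamber,
    simulate_cohort_table,
    simulate_dilution_series,
)


def test_poisson_occupancy_matches_closed_form(screening):
    """1000 WT copies in 20k partitions of 0.68 nL: ~536.7 FAM+Cy5+ droplets."""
    cfg = ChamberConfig(templates={"WT": 1000.0}, fp_rate={}, seed=11)
    lam = cfg.lambda_per_droplet(1000.0)
    assert lam == pytest.approx(0.0272)
    p = 1 - math.exp(-lam)
    expected = cfg.n_partitions * p
    assert expected == pytest.approx(536.7, abs=0.1)
    ds = simulate_chamber(cfg, screening)
    observed = int((ds.provenance["true_classes"] == "WT").sum())
    sigma = math.sqrt(cfg.n_partitions * p * (1 - p))
    assert abs(observed - expected) < 3 * sigma


def test_blank_chamber_is_all_empty(screening):
    cfg = ChamberConfig(templates={}, fp_rate={}, seed=1)
    ds = simulate_chamber(cfg, screening)
    assert set(ds.provenance["true_classes"]) == {"empty"}


def test_same_seed_is_byte_identical(screening):
    cfg = ChamberConfig(templates={"WT": 5000.0, "L755S": 50.0}, seed=42)
    a = simulate_chamber(cfg, screening, chamber_id="x")
    b = simulate_chamber(cfg, screening, chamber_id="x")
    pd.testing.assert_frame_equal(a.intensities, b.intensities)
    pd.testing.assert_frame_equal(a.provenance, b.provenance)
    c = simulate_chamber(cfg, screening, chamber_id="y")  # distinct chamber stream
    assert not a.intensities.equals(c.intensities)


def test_zero_partitions_with_templates_raises(screening):
    cfg = ChamberConfig(templates={"WT": 10.0}, n_partitions=0)
    with pytest.raises(ValueError, match="no partitions"):
        simulate_chamber(cfg, screening)


def test_unknown_species_raises(screening):
    with pytest.raises(ValueError, match="not in assay"):
        simulate_chamber(ChamberConfig(templates={"KRAS_G12D": 5.0}), screening)


def test_dilution_series_arithmetic(screening):
    base = ChamberConfig(seed=3)
    mafs = [5, 2.5, 1, 0.5, 0.25, 0.1, 0.05]
    series = simulate_dilution_series(
        base, mafs, design=screening, variant="V777M", wt_copies=10_000
    )
    # 3 replicates per level, 4 at 0.05%
    assert len(series) == 3 * 6 + 4
    by_level = {}
    for dc in series:
        by_level.setdefault(dc.theoretical_maf_pct, []).append(dc)
    assert len(by_level[0.05]) == 4
    # mutant copies: MAF/100 * 10,000 (5 at 0.05%, 500 at 5%)
    occ = by_level[0.05][0].droplets.provenance
    assert "occ_V777M" in occ  # species present even at 5 copies/PCR
    lam5 = ChamberConfig().lambda_per_droplet(5.0)
    assert occ["occ_V777M"].sum() <= 5 + 4 * math.sqrt(5)  # ~Poisson(N*lam)= ~4
    lam500 = ChamberConfig().lambda_per_droplet(500.0)
    occ5 = by_level[5][0].droplets.provenance["occ_V777M"].sum()
    n_expected = 20_000 * lam500  # only the partitioned fraction is analyzed
    assert abs(occ5 - n_expected) < 4 * math.sqrt(n_expected)


def test_dilution_series_requires_descending_positive_mafs(screening):
    with pytest.raises(ValueError):
        simulate_dilution_series(
            ChamberConfig(), [1, 5], design=screening, variant="V777M"
        )
    with pytest.raises(ValueError):
        simulate_dilution_series(
            ChamberConfig(), [-1.0], design=screening, variant="V777M"
        )


def test_blank_panel_mean_matches_rate(screening):
    cfg = ChamberConfig(
        templates={"WT": 10_000.0}, fp_rate={"776-779_MUT": 2.0}, seed=5
    )
    panel = simulate_blank_panel(cfg, n=10_000, design=screening, count_only=True)
    counts = panel.counts["776-779_MUT"]
    se = math.sqrt(2.0 / counts.size)
    assert abs(counts.mean() - 2.0) < 3 * se
    assert (panel.counts["S310F/Y"] == 0).all()  # rate not configured -> none


def test_blank_panel_zero_rate_all_zero(screening):
    cfg = ChamberConfig(templates={"WT": 10_000.0}, fp_rate={}, seed=5)
    panel = simulate_blank_panel(cfg, n=10, design=screening)
    for counts in panel.counts.values():
        assert (counts == 0).all()


def test_blank_panel_default_size_and_minimum(screening):
    cfg = ChamberConfig(templates={"WT": 10_000.0}, seed=5)
    panel = simulate_blank_panel(cfg, design=screening, count_only=True)
    assert panel.n_replicates == 34
    assert panel.background_copies_per_pcr == 10_000.0
    with pytest.raises(ValueError):
        simulate_blank_panel(cfg, n=1, design=screening)


def test_count_only_panel_matches_chamber_panel_distribution(screening):
    """The fast count path and the full chamber path draw the same FP model."""
    cfg = ChamberConfig(templates={"WT": 10_000.0}, seed=8)
    full = simulate_blank_panel(cfg, n=120, design=screening)
    fast = simulate_blank_panel(cfg, n=120, design=screening, count_only=True)
    for g in full.counts:
        rate_full = full.counts[g].mean()
        rate_fast = fast.counts[g].mean()
        se = math.sqrt(2 * max(rate_full, 0.1) / 120)
        assert abs(rate_full - rate_fast) < 4 * se


def test_cohort_prevalence_and_double_mutation_rate():
    table = simulate_cohort_table(n_patients=5000, prevalence=0.033, seed=9)
    positive = table[table["mutations"] != ""]
    n_pos = len(positive)
    expected = 5000 * 0.033
    assert abs(n_pos - expected) < 3 * math.sqrt(expected)
    n_two = (positive["mutations"].str.count(";") == 1).sum()
    p = n_two / n_pos
    assert abs(p - 1 / 3) < 3 * math.sqrt(p * (1 - p) / n_pos) + 0.02


def test_cohort_zero_prevalence():
    table = simulate_cohort_table(n_patients=200, prevalence=0.0, seed=2)
    assert (table["mutations"] == "").all()


def test_demo_cohort_shape():
    table = demo_cohort_table()
    assert len(table) == 272
    assert table["patient_id"].is_unique
    assert set(table["histology"]) == {"IBC-NST", "pure ILC", "mixed ILC"}
    mafs = [
        maf for cell in table["mutations"] for _, _, maf in parse_mutations(cell)
    ]
    assert all(0 <= m <= 100 for m in mafs)
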