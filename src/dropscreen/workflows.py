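"""End-to-end simulation workflows: generate chambers, gate, quantify, call.

These functions wire the synthetic generator through gating, limit
calibration and quantification exactly as a bench run would be analyzed, and
power the validation studies (linearity, reproducibility, dilution
sensitivity) and the two-step calling demonstrations.
"""

from __future__ import annotations

import numpy as np

from .assay import GROUP_HOTSPOT, AssayDesign, build_erbb2_assays
from .diagnose import SampleCall, limits_from_blanks, run_two_step
from .gating import GateSet, classify_droplets, correct_dup_overlap, derive_gates
from .limits import LimitEstimates
from .quantify import SamplePrep, concentration_from_counts
from .simulate import (
    ChamberConfig,
    DropletSet,
    positive_control_config,
    simulate_blank_panel,
    simulate_chamber,
    simulate_dilution_series,
)
from .stats import DilutionMeasurement, cv_percent, linearity_r2


def control_chamber(design: AssayDesign, seed: int = 0) -> DropletSet:
    """Positive-control chamber: WT gDNA plus every mutant gBlock."""
    cfg = positive_control_config(design, seed=seed)
    return simulate_chamber(cfg, design, chamber_id=f"{design.name}-control")


def default_gates(design: AssayDesign, seed: int = 0) -> GateSet:
    return derive_gates(control_chamber(design, seed=seed), design)


def screening_limits(
    seed: int = 0,
    n_blanks: int = 34,
    design: AssayDesign | None = None,
    n_partitions: int = 20_000,
) -> dict[str, LimitEstimates]:
    """Calibrate per-group limits from a simulated 34-replicate blank panel."""
    design = design or build_erbb2_assays()[0]
    cfg = ChamberConfig(templates={"WT": 10_000.0}, n_partitions=n_partitions, seed=seed)
    panel = simulate_blank_panel(cfg, n=n_blanks, design=design, count_only=True)
    return limits_from_blanks(panel, n_partitions=n_partitions)


def measured_copies_per_pcr(
    ds: DropletSet,
    gates: GateSet,
    group: str,
    mu_corr: float = 0.0,
    conditional: bool | None = None,
) -> float:
    """Gate one chamber and return the LOB-corrected load of one class."""
    cc = correct_dup_overlap(classify_droplets(ds, gates))
    if conditional is None:
        conditional = group == GROUP_HOTSPOT
    k_corr = max(0.0, cc.counts[group] - mu_corr)
    q = concentration_from_counts(
        cc, group, mode="conditional" if conditional else "naive", k_override=k_corr
    )
    return q.copies_per_pcr


def linearity_experiment(
    seed: int,
    variant: str = "L755S",
    levels: tuple[float, ...] = (5, 10, 50, 100, 500, 1000),
    replicates: int = 3,
    design: AssayDesign | None = None,
) -> float:
    """R^2 of measured vs expected copies/PCR over a simulated dilution range.

    Each level is assayed in ``replicates`` chambers; replicate estimates are
    averaged per level before the regression, as in standard assay-validation
    practice.
    """
    design = design or build_erbb2_assays()[0]
    gates = default_gates(design, seed=seed)
    lims = screening_limits(seed=seed, design=design)
    group = design.group_of(variant)
    mu_corr = lims[group].mu_corr
    expected, measured = [], []
    for level in levels:
        cfg = ChamberConfig(templates={variant: float(level)}, seed=seed)
        ests = [
            measured_copies_per_pcr(
                simulate_chamber(cfg, design, chamber_id=f"lin-{level}-r{r}"),
                gates, group, mu_corr,
            )
            for r in range(replicates)
        ]
        expected.append(level)
        measured.append(float(np.mean(ests)))
    return linearity_r2(expected, measured)


def reproducibility_experiment(
    seed: int,
    copies_per_pcr: float = 500.0,
    variant: str = "L755S",
    n_chambers: int = 8,
    design: AssayDesign | None = None,
) -> float:
    """Inter-assay CV% of the measured load across independent chambers."""
    design = design or build_erbb2_assays()[0]
    gates = default_gates(design, seed=seed)
    lims = screening_limits(seed=seed, design=design)
    group = design.group_of(variant)
    mu_corr = lims[group].mu_corr
    cfg = ChamberConfig(templates={variant: copies_per_pcr}, seed=seed)
    ests = [
        measured_copies_per_pcr(
            simulate_chamber(cfg, design, chamber_id=f"rep-{i}"), gates, group, mu_corr
        )
        for i in range(n_chambers)
    ]
    return cv_percent(ests)


def dilution_sensitivity_measurements(
    seed: int,
    variant: str,
    mafs: tuple[float, ...] = (5, 2.5, 1, 0.5, 0.25, 0.1, 0.05),
    design: AssayDesign | None = None,
    gates: GateSet | None = None,
    wt_copies: float = 10_000.0,
) -> list[DilutionMeasurement]:
    """Simulate the MAF ladder for one variant and gate every chamber."""
    design = design or build_erbb2_assays()[0]
    gates = gates or default_gates(design, seed=seed)
    group = design.group_of(variant)
    base = ChamberConfig(seed=seed)
    chambers = simulate_dilution_series(
        base, list(mafs), design=design, variant=variant, wt_copies=wt_copies
    )
    out = []
    for dc in chambers:
        cc = correct_dup_overlap(classify_droplets(dc.droplets, gates))
        k = cc.counts[group]
        conditional = group == GROUP_HOTSPOT
        q = concentration_from_counts(
            cc, group, mode="conditional" if conditional else "naive"
        )
        wt = concentration_from_counts(cc, "WT", mode="naive")
        maf = 100.0 * q.copies_per_pcr / max(q.copies_per_pcr + wt.copies_per_pcr, 1e-12)
        out.append(
            DilutionMeasurement(
                group=group,
                theoretical_maf_pct=dc.theoretical_maf_pct,
                replicate=dc.replicate,
                positive_droplets=int(k),
                measured_maf_pct=maf,
            )
        )
    return out


def simulate_patient_sample(
    variant_mafs: dict[str, float],
    seed: int = 0,
    wt_copies: float = 10_000.0,
    n_replicates: int = 1,
    sample_id: str = "sample",
    designs: tuple[AssayDesign, list[AssayDesign]] | None = None,
) -> tuple[list[DropletSet], dict[str, list[DropletSet]]]:
    """Screening replicates plus the matching duplex chambers for a sample.

    ``variant_mafs`` maps variant names to their true MAF (%); mutant copies
    are MAF/100 * wt_copies.  Duplex chambers are generated for every duplex
    covering a mutated screening group (as the two-step workflow would order
    them after a positive screen).
    """
    screening, duplexes = designs or build_erbb2_assays()
    templates = {"WT": wt_copies}
    for v, maf in variant_mafs.items():
        templates[v] = maf / 100.0 * wt_copies
    screen = [
        simulate_chamber(
            ChamberConfig(templates=templates, seed=seed),
            screening,
            chamber_id=f"{sample_id}-screen-r{i}",
        )
        for i in range(n_replicates)
    ]
    groups_hit = {screening.group_of(v) for v in variant_mafs}
    duplex_chambers: dict[str, list[DropletSet]] = {}
    for dup in duplexes:
        if dup.screen_group not in groups_hit:
            continue
        dtemplates = {"WT": wt_copies}
        for v, maf in variant_mafs.items():
            if v in dup.species:
                dtemplates[v] = maf / 100.0 * wt_copies
        ds = simulate_chamber(
            ChamberConfig(templates=dtemplates, seed=seed),
            dup,
            chamber_id=f"{sample_id}-{dup.name}",
        )
        duplex_chambers.setdefault(dup.screen_group, []).append(ds)
    return screen, duplex_chambers


def run_simulated_sample(
    variant_mafs: dict[str, float],
    seed: int = 0,
    n_replicates: int = 1,
    prep: SamplePrep | None = None,
    with_controls: bool = True,
) -> SampleCall:
    """Full two-step call on one simulated sample (gates, limits, controls)."""
    screening, duplexes = build_erbb2_assays()
    screen_gates = default_gates(screening, seed=seed)
    duplex_gates = {d.name: default_gates(d, seed=seed) for d in duplexes}
    lims = screening_limits(seed=seed, design=screening)
    prep = prep or SamplePrep(plasma_volume_ml=4.0)
    screen, duplex_chambers = simulate_patient_sample(
        variant_mafs, seed=seed, n_replicates=n_replicates, designs=(screening, duplexes)
    )
    neg = pos = None
    if with_controls:
        neg = simulate_chamber(
            ChamberConfig(templates={}, seed=seed), screening, chamber_id="neg-control"
        )
        pos = control_chamber(screening, seed=seed)
    return run_two_step(
        "sim-sample",
        screen,
        duplex_chambers,
        screen_gates,
        duplex_gates,
        lims,
        prep,
        negative_control=neg,
        positive_control=pos,
    )
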