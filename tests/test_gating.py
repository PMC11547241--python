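"""Gate derivation, droplet classification, and the dup/WT overlap correction."""

import numpy as np
import pytest

from dropscreen.assay import GROUP_DUP, GROUP_WT
from dropscreen.gating import (
    ClusterCounts,
    Gate,
    GateSet,
    classify_droplets,
    correct_dup_overlap,
    derive_gates,
)
from dropscreen.simulate import ChamberConfig, simulate_chamber
from dropscreen.workflows import control_chamber


def _truth_sets(ds):
    prov = ds.provenance
    out = []
    for cell in prov["true_classes"]:
        out.append(set() if cell == "empty" else set(cell.split("|")))
    return out


def test_derive_gates_covers_all_classes(screening, control, screen_gates):
    covered = {c for g in screen_gates.gates for c in g.classes}
    assert {g.name for g in screening.groups} <= covered
    # the two duplication species occupy distinct cluster positions
    dup_gates = [g for g in screen_gates.gates if g.classes == (GROUP_DUP,)]
    assert len(dup_gates) >= 2


def test_derive_gates_empty_control_raises(screening):
    blank = simulate_chamber(
        ChamberConfig(templates={}, fp_rate={}, seed=0), screening
    )
    with pytest.raises(ValueError, match="absent from control"):
        derive_gates(blank, screening)


def test_classification_accuracy_vs_provenance(screening, control, screen_gates):
    """>=99% of non-rain droplets fall in exactly their true class set."""
    _, member = classify_droplets(control, screen_gates, return_membership=True)
    prov = control.provenance
    usable = (~prov["is_rain"]).to_numpy()
    truth = _truth_sets(control)
    ok = total = 0
    for i in np.flatnonzero(usable):
        t = truth[i]
        if t == {"multi"}:
            continue
        got = {c for c, arr in member.items() if arr[i]}
        if GROUP_DUP in t:
            got.discard(GROUP_WT)  # expected superposition, removed downstream
        total += 1
        ok += got == t
    assert ok / total >= 0.99


def test_noise_free_classification_is_exact(screening):
    cfg = ChamberConfig(
        templates={"WT": 3000.0, "V777M": 300.0, "L755S": 300.0},
        noise_sd=0.0, rain_fraction=0.0, fp_rate={}, seed=21,
    )
    control = simulate_chamber(
        ChamberConfig(
            templates={sp: 500.0 for sp in screening.species} | {"WT": 5000.0},
            noise_sd=0.0, rain_fraction=0.0, fp_rate={}, seed=22,
        ),
        screening, chamber_id="nf-control",
    )
    gates = derive_gates(control, screening)
    ds = simulate_chamber(cfg, screening, chamber_id="nf")
    _, member = classify_droplets(ds, gates, return_membership=True)
    truth = _truth_sets(ds)
    for i in range(ds.n_partitions):
        t = truth[i]
        if t == {"multi"}:
            continue
        got = {c for c, arr in member.items() if arr[i]}
        if GROUP_DUP in t:
            got.discard(GROUP_WT)
        assert got == t


def test_droplet_conservation(screening, control, screen_gates):
    cc = classify_droplets(control, screen_gates)
    assert (
        sum(cc.counts.values()) - cc.n_multi + cc.unclassified + cc.empty
        == cc.total_partitions
    )
    corrected = correct_dup_overlap(cc)
    assert (
        sum(corrected.counts.values()) - corrected.n_multi
        + corrected.unclassified + corrected.empty
        == corrected.total_partitions
    )


def test_affine_rescaling_invariance(screening, control, screen_gates):
    """Same classification when gates come from an identically rescaled control."""
    scale, offset = 2.5, 400.0
    cc = classify_droplets(control, screen_gates)
    rescaled = control
    import copy

    rescaled = copy.copy(control)
    rescaled.intensities = control.intensities * scale + offset
    gates2 = screen_gates.rescaled(scale, offset)
    cc2 = classify_droplets(rescaled, gates2)
    assert cc.counts == cc2.counts
    assert cc.unclassified == cc2.unclassified


def test_dup_droplets_quantified_in_wt_gate_then_corrected(screening):
    """Triple-positive dup droplets sit inside the WT gate until corrected."""
    cfg = ChamberConfig(
        templates={"WT": 5000.0, "Y772_A775dup": 400.0}, fp_rate={}, seed=33
    )
    ds = simulate_chamber(cfg, screening, chamber_id="dupwt")
    control = control_chamber(screening, seed=0)
    gates = derive_gates(control, screening)
    raw = classify_droplets(ds, gates)
    prov = ds.provenance
    n_dup_true = int(
        prov["true_classes"].str.contains("dup", regex=False).sum()
    )
    assert raw.counts[GROUP_DUP] == pytest.approx(n_dup_true, abs=0.05 * n_dup_true + 10)
    # WT gate includes the dup droplets before correction
    corrected = correct_dup_overlap(raw)
    assert corrected.counts[GROUP_WT] == raw.counts[GROUP_WT] - raw.counts[GROUP_DUP]
    assert corrected.counts[GROUP_DUP] == raw.counts[GROUP_DUP]


def test_correct_dup_overlap_contract():
    base = dict(chamber_id="c", assay="a", total_partitions=10_000)
    cc = ClusterCounts(counts={GROUP_WT: 5000, GROUP_DUP: 100}, n_multi=100, **base)
    out = correct_dup_overlap(cc)
    assert out.counts[GROUP_WT] == 4900
    assert out.counts[GROUP_DUP] == 100
    # no dup droplets -> unchanged
    cc0 = ClusterCounts(counts={GROUP_WT: 5000, GROUP_DUP: 0}, **base)
    assert correct_dup_overlap(cc0).counts == cc0.counts
    # dup exceeding WT floors at zero with a warning
    ccf = ClusterCounts(counts={GROUP_WT: 10, GROUP_DUP: 25}, n_multi=10, **base)
    with pytest.warns(UserWarning, match="floored"):
        out = correct_dup_overlap(ccf)
    assert out.counts[GROUP_WT] == 0


def test_polygon_boundary_counts_inside():
    gate = Gate(
        name="g", classes=("X",), plane=("FAM", "Cy5"),
        vertices=[(0, 0), (10, 0), (10, 10), (0, 10)],
    )
    gates = GateSet(
        gates=[gate], precedence=["g"],
        empty_thresholds={"FAM": -100.0, "HEX": -100.0, "Cy5": -100.0},
    )
    import pandas as pd

    from dropscreen.simulate import DropletSet

    ds = DropletSet(
        chamber_id="b", assay="a", n_partitions=3,
        droplet_volume_nl=0.68, reaction_volume_ul=25.0,
        intensities=pd.DataFrame(
            {"fam": [10.0, 5.0, 11.0], "hex": [0.0, 0.0, 0.0], "cy5": [5.0, 5.0, 5.0]}
        ),
    )
    cc = classify_droplets(ds, gates)
    assert cc.counts["X"] == 2  # boundary point (10,5) is inside; (11,5) is not


def test_gate_polygon_validation():
    with pytest.raises(ValueError, match="3 vertices"):
        Gate(name="g", classes=("X",), plane=("FAM", "Cy5"), vertices=[(0, 0), (1, 1)])
    with pytest.raises(ValueError, match="self-intersecting"):
        Gate(
            name="g", classes=("X",), plane=("FAM", "Cy5"),
            vertices=[(0, 0), (10, 10), (10, 0), (0, 10)],
        )
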