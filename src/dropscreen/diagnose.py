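"""Reaction planning, replicate positivity rule, and the two-step caller.

The diagnostic strategy is screen-then-identify: the multiplex screening
assay flags which detection group (if any) carries signal; each positive
group is followed up with the corresponding WT-MUT duplex assay(s), which
pin down the exact variant and provide the final quantities (copies/mL of
plasma, MAF%).

Positivity rule: a detection with at least two replicates at or above the
LOD95 droplet count is positive; all replicates at or below the LOB95 is
negative; counts between LOB and LOD are equivocal and trigger a structured
recommendation to rerun with additional replicates.  Every run carries a
negative (H2O) and a positive control chamber; calls from runs with failed
controls are suppressed, not silently emitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .assay import GROUP_HOTSPOT, GROUP_WT, MutationID, normalize_variant_name
from .gating import ClusterCounts, GateSet, classify_droplets, correct_dup_overlap
from .limits import LimitEstimates
from .quantify import (
    QuantResult,
    SamplePrep,
    compute_maf,
    concentration_from_counts,
    copies_per_ml_plasma,
    pool_replicates,
)
from .simulate import PG_PER_COPY, BlankPanel, DropletSet

MAX_INPUT_NG_PER_PCR = 33.0       # caps the reaction at 10,000 copies/PCR
MIN_TOTAL_NG = 10.0               # replicate until at least this much is assayed
INPUT_UL_PER_PCR = 15.0


@dataclass
class ReactionPlan:
    dilution_factor: float
    n_replicates: int
    input_ng_per_pcr: float
    projected_copies_per_pcr: float

    def __post_init__(self) -> None:
        if self.projected_copies_per_pcr > 10_000 + 1e-9:
            raise ValueError("plan exceeds the 10,000 copies/PCR input cap")


def plan_reaction(cfdna_ng_per_ul: float, available_ul: float = 45.0) -> ReactionPlan:
    """Choose dilution and replicate count for a cfDNA sample.

    Highly concentrated samples are diluted so the 15 uL input carries at most
    33 ng (10,000 copies at 3.3 pg per haploid genome equivalent); low
    concentrations are assayed in up to three replicates until at least 10 ng
    total is investigated or the material is exhausted.
    """
    if cfdna_ng_per_ul < 0 or available_ul < 0:
        raise ValueError("concentration and volume must be >= 0")
    ng_per_input = cfdna_ng_per_ul * INPUT_UL_PER_PCR
    dilution = max(1.0, ng_per_input / MAX_INPUT_NG_PER_PCR)
    input_ng = min(ng_per_input, MAX_INPUT_NG_PER_PCR)
    ul_per_replicate = INPUT_UL_PER_PCR / dilution  # undiluted sample consumed
    n = 1
    while (
        n < 3
        and n * input_ng < MIN_TOTAL_NG
        and (n + 1) * ul_per_replicate <= available_ul
    ):
        n += 1
    return ReactionPlan(
        dilution_factor=dilution,
        n_replicates=n,
        input_ng_per_pcr=input_ng,
        projected_copies_per_pcr=input_ng * 1000.0 / PG_PER_COPY,
    )


@dataclass
class GroupCall:
    group: str
    replicate_counts: list[int]
    status: str  # negative | equivocal | positive
    recommended_additional_replicates: int = 0
    quant: QuantResult | None = None


@dataclass
class SampleCall:
    sample_id: str
    screen: list[GroupCall] = field(default_factory=list)
    identified: list[tuple[MutationID, QuantResult]] = field(default_factory=list)
    controls_ok: bool = True
    status: str = "ok"  # ok | invalid-controls | incomplete | unconfirmed

    @property
    def positive_groups(self) -> list[str]:
        return [g.group for g in self.screen if g.status == "positive"]


def call_detection_group(replicate_counts: list[int], limits: LimitEstimates) -> GroupCall:
    """Apply the replicate positivity rule to raw per-replicate droplet counts."""
    if not replicate_counts:
        raise ValueError("at least one replicate count is required")
    lob, lod = limits.lob95_droplets, limits.lod95_droplets
    counts = list(replicate_counts)
    if len(counts) == 1:
        c = counts[0]
        if c <= lob:
            status, extra = "negative", 0
        elif c >= lod:
            # accepted for high-concentration single-replicate assays
            status, extra = "positive", 0
        else:
            status, extra = "equivocal", 2
    else:
        n_lod = sum(c >= lod for c in counts)
        if n_lod >= 2:
            status, extra = "positive", 0
        elif all(c <= lob for c in counts):
            status, extra = "negative", 0
        else:
            status, extra = "equivocal", (1 if len(counts) == 2 else 0)
    return GroupCall(
        group=limits.group,
        replicate_counts=counts,
        status=status,
        recommended_additional_replicates=extra,
    )


def quantify_group(
    pooled: ClusterCounts,
    group: str,
    mu_corr: float,
    n_replicates: int,
    prep: SamplePrep | None = None,
    conditional: bool | None = None,
) -> QuantResult:
    """LOB-corrected concentration, MAF and copies/mL for one detection class.

    The corrected blank mean scales with the number of pooled replicates.
    The drop-off hotspot class uses the conditional estimator; all other
    classes sit on their own amplicons, where wild type produces no signal,
    and use the naive estimator.
    """
    if conditional is None:
        conditional = group == GROUP_HOTSPOT
    k_raw = pooled.counts[group]
    k_corr = max(0.0, k_raw - mu_corr * n_replicates)
    q = concentration_from_counts(
        pooled, group, mode="conditional" if conditional else "naive", k_override=k_corr
    )
    wt = concentration_from_counts(pooled, GROUP_WT, mode="naive")
    if q.copies_per_pcr > 0 or wt.copies_per_pcr > 0:
        q.maf_pct = compute_maf(q.copies_per_pcr, wt.copies_per_pcr)
    if prep is not None:
        q.copies_per_ml = copies_per_ml_plasma(q, prep)
    return q


def _check_controls(
    gates: GateSet,
    limits: dict[str, LimitEstimates],
    negative_control: DropletSet | None,
    positive_control: DropletSet | None,
) -> bool:
    ok = True
    if negative_control is not None:
        cc = correct_dup_overlap(classify_droplets(negative_control, gates))
        for g, lim in limits.items():
            if cc.counts.get(g, 0) > lim.lob95_droplets:
                ok = False
    if positive_control is not None:
        cc = correct_dup_overlap(classify_droplets(positive_control, gates))
        for g, lim in limits.items():
            if cc.counts.get(g, 0) < lim.lod95_droplets:
                ok = False
    return ok


def run_two_step(
    sample_id: str,
    screen_chambers: list[DropletSet],
    duplex_chambers_by_group: dict[str, list[DropletSet]],
    screen_gates: GateSet,
    duplex_gates: dict[str, GateSet],
    limits: dict[str, LimitEstimates],
    prep: SamplePrep,
    negative_control: DropletSet | None = None,
    positive_control: DropletSet | None = None,
) -> SampleCall:
    """Screen a sample, then identify mutations in positive groups via duplexes.

    ``duplex_gates`` is keyed by duplex assay name (each duplex DropletSet
    carries its assay in metadata).  Duplex calls reuse the screening group's
    droplet limits.  Final quantities for identified mutations come from the
    identifying duplex; screening-level quantities stay attached to the
    screen GroupCalls for cross-checking.
    """
    if not _check_controls(screen_gates, limits, negative_control, positive_control):
        return SampleCall(sample_id=sample_id, controls_ok=False, status="invalid-controls")

    per_chamber = [
        correct_dup_overlap(classify_droplets(ch, screen_gates)) for ch in screen_chambers
    ]
    pooled = pool_replicates(per_chamber)
    n_rep = len(per_chamber)

    call = SampleCall(sample_id=sample_id)
    for group, lim in limits.items():
        gc = call_detection_group([cc.counts.get(group, 0) for cc in per_chamber], lim)
        if gc.status == "positive":
            gc.quant = quantify_group(pooled, group, lim.mu_corr, n_rep, prep)
        call.screen.append(gc)

    for group in call.positive_groups:
        chambers = duplex_chambers_by_group.get(group, [])
        if not chambers:
            call.status = "incomplete"
            continue
        lim = limits[group]
        confirmed_any = False
        by_assay: dict[str, list[DropletSet]] = {}
        for ch in chambers:
            by_assay.setdefault(ch.assay, []).append(ch)
        for assay_name, reps in by_assay.items():
            gates = duplex_gates[assay_name]
            counts = [classify_droplets(ch, gates) for ch in reps]
            dpooled = pool_replicates(counts)
            for variant in (c for c in gates.classes if c != GROUP_WT):
                gc = call_detection_group([cc.counts.get(variant, 0) for cc in counts], lim)
                if gc.status != "positive":
                    continue
                q = quantify_group(
                    dpooled, variant, lim.mu_corr, len(reps), prep, conditional=False
                )
                call.identified.append((normalize_variant_name(variant), q))
                confirmed_any = True
        if not confirmed_any and call.status == "ok":
            call.status = "unconfirmed"
    return call


def limits_from_blanks(
    blanks: BlankPanel,
    n_partitions: int = 20_000,
    droplet_volume_nl: float = 0.68,
    reaction_volume_ul: float = 25.0,
) -> dict[str, LimitEstimates]:
    """Per-group single-replicate limits from a blank panel."""
    from .limits import estimate_limits

    return {
        g: estimate_limits(
            c, g, n_partitions, droplet_volume_nl, reaction_volume_ul,
            wt_background_copies=blanks.background_copies_per_pcr,
        )
        for g, c in blanks.counts.items()
    }
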