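"""Polygon gating of droplets on 2D channel planes.

Gates mirror manual practice on the instrument software: polygons drawn on
2D dot plots (FAM x Cy5, FAM x HEX) around the positive-control cluster
positions.  A droplet is tested against gates plane by plane in precedence
order; membership is boundary-inclusive (even-odd rule).  Because a droplet
can legitimately satisfy gates on different planes (it may hold templates of
two species), per-class counts are membership counts: the duplication
cluster, for instance, is FAM+Cy5+ and therefore also falls inside the WT
gate on the FAM-Cy5 plane — the overlap the dup/WT correction removes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import shapely

from .assay import GROUP_DUP, GROUP_WT, AssayDesign, cluster_positions
from .simulate import DropletSet

_CHANNEL_COLS = {"FAM": "fam", "HEX": "hex", "Cy5": "cy5"}


@dataclass
class Gate:
    name: str
    classes: tuple[str, ...]
    plane: tuple[str, str]
    vertices: list[tuple[float, float]]

    def __post_init__(self) -> None:
        if len(self.vertices) < 3:
            raise ValueError("a gate polygon needs at least 3 vertices")
        if not np.isfinite(np.asarray(self.vertices, dtype=float)).all():
            raise ValueError("gate vertices must be finite")
        if not self.polygon.is_valid:
            raise ValueError(f"gate {self.name!r}: polygon is self-intersecting")

    @property
    def polygon(self) -> shapely.Polygon:
        return shapely.Polygon(self.vertices)


@dataclass
class GateSet:
    gates: list[Gate]
    precedence: list[str]
    empty_thresholds: dict[str, float]  # channel -> "above baseline" cutoff
    assay: str = ""

    def __post_init__(self) -> None:
        names = [g.name for g in self.gates]
        if set(names) - set(self.precedence):
            raise ValueError("precedence must cover all gates")

    @property
    def classes(self) -> tuple[str, ...]:
        out: list[str] = []
        for g in self.gates:
            for c in g.classes:
                if c not in out:
                    out.append(c)
        return tuple(out)

    def rescaled(self, scale: float, offset: float) -> "GateSet":
        """Apply the affine map x -> scale*x + offset to every vertex/threshold."""
        gates = [
            replace(g, vertices=[(scale * x + offset, scale * y + offset) for x, y in g.vertices])
            for g in self.gates
        ]
        thr = {c: scale * v + offset for c, v in self.empty_thresholds.items()}
        return GateSet(gates=gates, precedence=list(self.precedence),
                       empty_thresholds=thr, assay=self.assay)


@dataclass
class ClusterCounts:
    """Droplets per detection class for one chamber (or a replicate pool).

    ``counts`` are per-class membership tallies; ``n_multi`` is the number of
    extra memberships carried by droplets that belong to more than one class
    (co-occupancy, or the dup/WT superposition before correction), so that

        sum(counts) - n_multi + unclassified + empty == total_partitions
    """

    chamber_id: str
    assay: str
    total_partitions: int
    counts: dict[str, int]
    unclassified: int = 0
    empty: int = 0
    n_multi: int = 0
    droplet_volume_nl: float = 0.68
    reaction_volume_ul: float = 25.0
    provenance_ids: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("class counts must be >= 0")


def derive_gates(
    control: DropletSet,
    design: AssayDesign,
    min_droplets: int = 10,
    margin_sigmas: float = 6.0,
    min_halfwidth: float = 250.0,
) -> GateSet:
    """Build rectangular polygon gates around the control chamber's clusters.

    The control must be a simulated positive control carrying every species of
    the design (WT gDNA plus mutant gBlocks): gates are anchored on the
    cluster centroids found there, one polygon per occupied cluster position,
    each tagged with the detection class(es) its droplets count toward.
    Margins are ``margin_sigmas`` times the observed cluster spread per axis,
    never narrower than ``min_halfwidth`` intensity units.
    """
    if control.provenance is None:
        raise ValueError("gate derivation needs a control with simulation provenance")
    prov = control.provenance
    inten = control.intensities
    usable = ~prov["is_rain"] & ~prov["is_fp"]

    registry = {cp.name: cp for cp in cluster_positions(design)}
    gates: list[Gate] = []
    for name, cp in registry.items():
        mask = usable & (prov["cluster"] == name)
        if int(mask.sum()) < min_droplets:
            continue
        primary = next((c for c in cp.classes if c != GROUP_WT), cp.classes[0])
        plane = design.plane_of(primary)
        x = inten.loc[mask, _CHANNEL_COLS[plane[0]]].to_numpy()
        y = inten.loc[mask, _CHANNEL_COLS[plane[1]]].to_numpy()
        hx = max(margin_sigmas * float(x.std()), min_halfwidth)
        hy = max(margin_sigmas * float(y.std()), min_halfwidth)
        cx, cy = float(x.mean()), float(y.mean())
        verts = [(cx - hx, cy - hy), (cx + hx, cy - hy), (cx + hx, cy + hy), (cx - hx, cy + hy)]
        gates.append(Gate(name=f"{name}-gate", classes=cp.classes, plane=plane, vertices=verts))

    covered = {c for g in gates for c in g.classes}
    for group in design.groups:
        if group.name not in covered:
            raise ValueError(
                f"required cluster for detection class {group.name!r} absent from control"
            )

    empty_mask = prov["cluster"] == "empty"
    if not empty_mask.any():
        raise ValueError("control chamber has no empty droplets to set baseline thresholds")
    thresholds = {}
    for ch, col in _CHANNEL_COLS.items():
        vals = inten.loc[empty_mask, col].to_numpy()
        thresholds[ch] = float(vals.mean()) + max(margin_sigmas * float(vals.std()), min_halfwidth)

    # mutant gates first so that same-plane ties resolve away from WT
    order = sorted(gates, key=lambda g: (GROUP_WT in g.classes, g.name))
    return GateSet(
        gates=gates,
        precedence=[g.name for g in order],
        empty_thresholds=thresholds,
        assay=design.name,
    )


def classify_droplets(
    ds: DropletSet, gates: GateSet, return_membership: bool = False
):
    """Count droplets per detection class by polygon membership.

    Within one plane, overlapping gates are resolved first-wins in precedence
    order; across planes memberships accumulate (a droplet holding two
    template species is a member of both classes).  Droplets in no gate are
    split into empty (all channels at baseline per the gate set's thresholds)
    and unclassified rain.
    """
    n = ds.n_partitions
    cols = {ch: ds.intensities[col].to_numpy() for ch, col in _CHANNEL_COLS.items()}
    member: dict[str, np.ndarray] = {c: np.zeros(n, dtype=bool) for c in gates.classes}
    by_name = {g.name: g for g in gates.gates}

    planes = {g.plane for g in gates.gates}
    for plane in planes:
        assigned = np.zeros(n, dtype=bool)
        for name in gates.precedence:
            g = by_name[name]
            if g.plane != plane:
                continue
            inside = shapely.intersects_xy(g.polygon, cols[plane[0]], cols[plane[1]])
            inside &= ~assigned
            assigned |= inside
            for c in g.classes:
                member[c] |= inside

    membership = np.column_stack([member[c] for c in gates.classes]) if member else np.zeros((n, 0), bool)
    per_droplet = membership.sum(axis=1)
    in_any = per_droplet > 0
    above = np.zeros(n, dtype=bool)
    for ch in _CHANNEL_COLS:
        above |= cols[ch] > gates.empty_thresholds[ch]
    unclassified = int((~in_any & above).sum())
    empty = int((~in_any & ~above).sum())

    counts = ClusterCounts(
        chamber_id=ds.chamber_id,
        assay=ds.assay,
        total_partitions=n,
        counts={c: int(member[c].sum()) for c in gates.classes},
        unclassified=unclassified,
        empty=empty,
        n_multi=int((per_droplet[in_any] - 1).sum()),
        droplet_volume_nl=ds.droplet_volume_nl,
        reaction_volume_ul=ds.reaction_volume_ul,
        provenance_ids=(ds.chamber_id,),
    )
    if return_membership:
        return counts, {c: member[c] for c in gates.classes}
    return counts


def correct_dup_overlap(raw: ClusterCounts) -> ClusterCounts:
    """Remove the duplication droplets that were also tallied in the WT gate.

    Duplication-bearing droplets keep the drop-off site intact and are
    FAM+Cy5+ — superimposed on the WT cluster in the FAM-Cy5 plane and hence
    quantified in the WT gate as well as in their own FAM-HEX gate.  The
    correction removes the dup-gate tally from the WT tally so no droplet
    contributes to both classes; the dup count itself is untouched.  The
    corrected WT count is floored at zero (with a warning, as that indicates
    inconsistent gating).
    """
    if GROUP_WT not in raw.counts or GROUP_DUP not in raw.counts:
        return raw
    dup = raw.counts[GROUP_DUP]
    wt = raw.counts[GROUP_WT]
    corrected = wt - dup
    if corrected < 0:
        warnings.warn(
            f"dup-gate count ({dup}) exceeds WT-gate count ({wt}); WT floored at 0",
            stacklevel=2,
        )
        corrected = 0
    new_counts = dict(raw.counts)
    new_counts[GROUP_WT] = corrected
    return replace(raw, counts=new_counts, n_multi=max(0, raw.n_multi - (wt - corrected)))
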