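"""Assay definitions and three-color decode logic for the ERBB2 screening test.

The screening multiplex amplifies four amplicons in every partition and reads
them out on three fluorescence channels (FAM, HEX, Cy5).  A drop-off probe
(FAM) together with a reference probe (Cy5) covers the codon 776-779 hotspot:
wild-type templates light both probes, any substitution under the drop-off
probe extinguishes FAM and leaves a Cy5-only signal.  Two further grouped
detections use FAM (S310F/Y) and HEX (L755S-D769H/Y-L869R) mutation-specific
probes, and two HEX probes flag the exon-20 duplications, which keep the
drop-off site intact and therefore show up triple-positive.

Assay content (amplicons, probes, detection groups, alias table) is data,
packaged as JSON, so that additional assays can be described without code
changes.  The six confirmatory WT-MUT duplexes share the same machinery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterator

CHANNELS = ("FAM", "HEX", "Cy5")

# Canonical detection-group labels of the screening assay.
GROUP_WT = "WT"
GROUP_S310 = "S310F/Y"
GROUP_KD = "L755S-D769H/Y-L869R"
GROUP_DUP = "Y772_A775dup-G778_P780dup"
GROUP_HOTSPOT = "776-779_MUT"
CLASS_HOTSPOT_PLUS_DUP = "776-779_MUT+dup"

SCREEN_GROUPS = (GROUP_S310, GROUP_KD, GROUP_DUP, GROUP_HOTSPOT)


@dataclass(frozen=True)
class ProbeSpec:
    name: str
    channel: str
    role: str  # mutation-specific | drop-off | reference | wild-type
    targets: tuple[str, ...]
    amplitude: float  # default cluster amplitude used by the synthetic generator

    def __post_init__(self) -> None:
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}; must be one of {CHANNELS}")


@dataclass(frozen=True)
class AmpliconSpec:
    id: str
    codon_range: tuple[int, int]
    probes: tuple[ProbeSpec, ...]

    def __post_init__(self) -> None:
        if self.codon_range[0] > self.codon_range[1]:
            raise ValueError("codon_range start must be <= end")


@dataclass(frozen=True)
class DetectionGroup:
    name: str
    member_variants: tuple[str, ...]
    plane: tuple[str, str] = ("FAM", "Cy5")


@dataclass(frozen=True)
class ClusterSignature:
    fam: bool
    hex: bool
    cy5: bool
    amplicon_context: str


@dataclass(frozen=True)
class MutationID:
    protein_name: str
    cdna_name: str = ""
    aliases: tuple[str, ...] = ()


@dataclass(frozen=True)
class ClusterPos:
    """Noise-free cluster position implied by one template-occupancy pattern."""

    name: str
    pattern: tuple[str, ...]           # template species generating the cluster
    classes: tuple[str, ...]           # detection classes the cluster counts toward
    fam: float
    hex: float
    cy5: float

    def coords(self, plane: tuple[str, str]) -> tuple[float, float]:
        by = {"FAM": self.fam, "HEX": self.hex, "Cy5": self.cy5}
        return by[plane[0]], by[plane[1]]


@dataclass
class AssayDesign:
    name: str
    amplicons: tuple[AmpliconSpec, ...]
    groups: tuple[DetectionGroup, ...]
    decode_table: dict[str, dict[tuple[bool, bool, bool], str]]
    variants: dict[str, MutationID] = field(default_factory=dict)
    aliases: dict[str, str] = field(default_factory=dict)
    kind: str = "screening"
    screen_group: str = ""  # for duplexes: the screening group they confirm

    # -- convenience views -------------------------------------------------
    @property
    def species(self) -> tuple[str, ...]:
        """All template species the design reacts to (wild type first)."""
        out = ["WT"]
        for g in self.groups:
            for m in g.member_variants:
                if m != "WT" and m not in out:
                    out.append(m)
        return tuple(out)

    def group_of(self, variant: str) -> str:
        for g in self.groups:
            if variant in g.member_variants:
                return g.name
        raise KeyError(f"{variant!r} is not detected by assay {self.name!r}")

    def plane_of(self, group: str) -> tuple[str, str]:
        for g in self.groups:
            if g.name == group:
                return g.plane
        raise KeyError(f"no detection group {group!r} in assay {self.name!r}")

    def iter_probes(self) -> Iterator[tuple[str, ProbeSpec]]:
        for amp in self.amplicons:
            for p in amp.probes:
                yield amp.id, p

    def validate(self) -> None:
        """Check structural invariants; raise ValueError on the first failure."""
        seen: dict[str, str] = {}
        for g in self.groups:
            if g.name == GROUP_WT:
                continue
            for m in g.member_variants:
                if m in seen:
                    raise ValueError(f"variant {m} in two groups: {seen[m]} and {g.name}")
                seen[m] = g.name
        probe_targets = {t for _, p in self.iter_probes() for t in p.targets}
        missing = set(seen) - probe_targets
        if missing:
            raise ValueError(f"variants without any probe: {sorted(missing)}")


def _load_raw() -> dict:
    with resources.files("dropscreen.data").joinpath("erbb2_assays.json").open() as fh:
        return json.load(fh)


def _probe(d: dict) -> ProbeSpec:
    return ProbeSpec(
        name=d["name"], channel=d["channel"], role=d["role"],
        targets=tuple(d["targets"]), amplitude=float(d["amplitude"]),
    )


def _amplicon(d: dict) -> AmpliconSpec:
    return AmpliconSpec(id=d["id"], codon_range=tuple(d["codon_range"]),
                        probes=tuple(_probe(p) for p in d["probes"]))


def _screening_decode(amplicons: tuple[AmpliconSpec, ...]) -> dict:
    """Three-color truth table per amplicon context for the screening design."""
    table: dict[str, dict[tuple[bool, bool, bool], str]] = {}
    for amp in amplicons:
        t: dict[tuple[bool, bool, bool], str] = {}
        roles = {p.role for p in amp.probes}
        channels = {p.channel for p in amp.probes}
        for f in (False, True):
            for h in (False, True):
                for c in (False, True):
                    t[(f, h, c)] = "unclassified"
        t[(False, False, False)] = "empty"
        if "drop-off" in roles:  # the 772-780 amplicon (six decode cases)
            t[(True, False, True)] = GROUP_WT
            t[(False, False, True)] = GROUP_HOTSPOT
            t[(False, True, True)] = CLASS_HOTSPOT_PLUS_DUP
            t[(True, True, True)] = GROUP_DUP
        elif channels == {"FAM"}:
            t[(True, False, False)] = GROUP_S310
        elif channels == {"HEX"}:
            t[(False, True, False)] = GROUP_KD
        table[amp.id] = t
    return table


def _duplex_decode(amp: AmpliconSpec, mut_members: tuple[str, ...]) -> dict:
    mut_label = mut_members[0] if len(mut_members) == 1 else "MUT"
    t: dict[tuple[bool, bool, bool], str] = {}
    for f in (False, True):
        for h in (False, True):
            for c in (False, True):
                t[(f, h, c)] = "unclassified"
    t[(False, False, False)] = "empty"
    t[(False, True, False)] = GROUP_WT
    t[(True, False, False)] = mut_label
    t[(True, True, False)] = f"{mut_label}+WT"
    return {amp.id: t}


def _variant_ids(raw: dict) -> tuple[dict[str, MutationID], dict[str, str]]:
    variants: dict[str, MutationID] = {}
    aliases: dict[str, str] = {}
    for name, info in raw["variants"].items():
        variants[name] = MutationID(protein_name=name, cdna_name=info.get("cdna", ""),
                                    aliases=tuple(info.get("aliases", ())))
        aliases[name.lower()] = name
        for a in info.get("aliases", ()):
            aliases[a.lower()] = name
    return variants, aliases


def build_erbb2_assays() -> tuple[AssayDesign, list[AssayDesign]]:
    """Load the packaged ERBB2 screening design and its six WT-MUT duplexes."""
    raw = _load_raw()
    variants, aliases = _variant_ids(raw)

    s = raw["screening"]
    amplicons = tuple(_amplicon(a) for a in s["amplicons"])
    groups = tuple(
        DetectionGroup(name=g["name"], member_variants=tuple(g["members"]),
                       plane=tuple(g.get("plane", ("FAM", "Cy5"))))
        for g in s["groups"]
    )
    screening = AssayDesign(
        name=s["name"], amplicons=amplicons, groups=groups,
        decode_table=_screening_decode(amplicons),
        variants=variants, aliases=aliases, kind="screening",
    )
    screening.validate()

    duplexes: list[AssayDesign] = []
    for d in raw["duplexes"]:
        amp = _amplicon(d["amplicon"])
        mut_members = tuple(
            t for p in amp.probes if p.role == "mutation-specific" for t in p.targets
        )
        dgroups = [DetectionGroup(name=GROUP_WT, member_variants=("WT",), plane=("FAM", "HEX"))]
        dgroups += [DetectionGroup(name=m, member_variants=(m,), plane=("FAM", "HEX"))
                    for m in mut_members]
        duplex = AssayDesign(
            name=d["name"], amplicons=(amp,), groups=tuple(dgroups),
            decode_table=_duplex_decode(amp, mut_members),
            variants=variants, aliases=aliases,
            kind="duplex", screen_group=d["screen_group"],
        )
        duplex.validate()
        duplexes.append(duplex)
    return screening, duplexes


def decode_signature(sig: ClusterSignature, design: AssayDesign) -> str:
    """Map a boolean three-channel signature to its detection-class label.

    The signature is interpreted in the context of one amplicon; intensity
    semantics (cluster positions, rain) live entirely in :mod:`dropscreen.gating`.
    """
    try:
        table = design.decode_table[sig.amplicon_context]
    except KeyError:
        raise KeyError(
            f"amplicon context {sig.amplicon_context!r} is not part of assay "
            f"{design.name!r} (known: {sorted(design.decode_table)})"
        ) from None
    return table[(sig.fam, sig.hex, sig.cy5)]


_DEFAULT_DESIGN: AssayDesign | None = None


def _default_design() -> AssayDesign:
    global _DEFAULT_DESIGN
    if _DEFAULT_DESIGN is None:
        _DEFAULT_DESIGN = build_erbb2_assays()[0]
    return _DEFAULT_DESIGN


def normalize_variant_name(alias: str, design: AssayDesign | None = None) -> MutationID:
    """Resolve a (possibly legacy) variant name to its recommended nomenclature.

    Exon-20 duplications circulate under legacy insertion names
    (A775-G776insYVMA for Y772_A775dup, P780_Y781insGSP for G778_P780dup);
    lookup is case-insensitive and idempotent on canonical names.
    """
    if not alias or not alias.strip():
        raise ValueError("variant name must be non-empty")
    design = design or _default_design()
    key = alias.strip().lower()
    if key in design.aliases:
        return design.variants[design.aliases[key]]
    known = sorted(design.variants)
    raise KeyError(f"unrecognized variant name {alias!r}; known names: {known}")


def cluster_positions(design: AssayDesign) -> list[ClusterPos]:
    """Enumerate the noise-free cluster positions reachable in a chamber.

    Patterns considered are single-species occupancies and mutant+WT
    co-occupancies; positions are per-channel sums of the amplitudes of all
    probes fired by any template in the droplet.  Patterns that collapse onto
    the position of a smaller pattern are dropped: this is exactly the
    drop-off masking (a droplet holding wild type plus a 776-779 substitution
    is indistinguishable from wild type alone) and the analogous duplication
    ambiguity, which downstream quantification corrects for.
    """
    species = design.species
    probes = [(amp, p) for amp, p in design.iter_probes()]

    def position(pattern: tuple[str, ...]) -> tuple[float, float, float]:
        by = {"FAM": 0.0, "HEX": 0.0, "Cy5": 0.0}
        present = set(pattern)
        for _, p in probes:
            if present & set(p.targets):
                by[p.channel] += p.amplitude
        return by["FAM"], by["HEX"], by["Cy5"]

    def classes(pattern: tuple[str, ...]) -> tuple[str, ...]:
        out: list[str] = []
        for sp in pattern:
            g = design.group_of(sp)
            if g not in out:
                out.append(g)
        return tuple(out)

    patterns: list[tuple[str, ...]] = [(sp,) for sp in species]
    patterns += [(sp, "WT") for sp in species if sp != "WT"]
    # both duplications together remain decodable (distinct HEX sum)
    dup_species = [sp for sp in species if "dup" in sp]
    if len(dup_species) == 2:
        patterns.append(tuple(dup_species))

    registry: dict[tuple[int, int, int], ClusterPos] = {}
    for pattern in sorted(patterns, key=len):
        f, h, c = position(pattern)
        key = (round(f), round(h), round(c))
        if key == (0, 0, 0) or key in registry:  # empty or masked by smaller pattern
            continue
        registry[key] = ClusterPos(
            name="+".join(pattern), pattern=pattern, classes=classes(pattern),
            fam=f, hex=h, cy5=c,
        )
    return list(registry.values())
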