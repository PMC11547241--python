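"""Validation statistics (CV, linearity, sensitivity) and cohort summaries."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .limits import LimitEstimates
from .simulate import COHORT_COLUMNS, parse_mutations


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (9/272 -> 3.3%, 2/12 -> 16.67%)."""
    factor = 10 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def cv_percent(values: Sequence[float]) -> float:
    """Coefficient of variation: 100 * sigma / mu with the sample SD."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("CV needs at least 2 values")
    mu = arr.mean()
    if mu == 0:
        raise ValueError("CV undefined for zero mean")
    return 100.0 * arr.std(ddof=1) / mu


def linearity_r2(expected: Sequence[float], measured: Sequence[float]) -> float:
    """Coefficient of determination of the OLS fit of measured on expected."""
    x = np.asarray(expected, dtype=float)
    y = np.asarray(measured, dtype=float)
    if x.size != y.size:
        raise ValueError("expected and measured must pair up")
    if x.size < 3:
        raise ValueError("linearity needs at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("degenerate design: expected values are constant")
    coef = np.polyfit(x, y, 1)
    resid = y - np.polyval(coef, x)
    sstot = float(((y - y.mean()) ** 2).sum())
    if sstot == 0:
        return 1.0
    return 1.0 - float((resid**2).sum()) / sstot


# ---------------------------------------------------------------------------
# dilution-series sensitivity
# ---------------------------------------------------------------------------


@dataclass
class DilutionMeasurement:
    """One replicate of one dilution level for one detection group."""

    group: str
    theoretical_maf_pct: float
    replicate: int
    positive_droplets: int
    measured_maf_pct: float


@dataclass
class GroupSensitivity:
    group: str
    per_dilution_mafs: dict[float, list[float]]
    detected: bool
    lowest_positive_maf_pct: float | None = None
    sensitivity_pct: float | None = None


def sensitivity_from_dilutions(
    measurements: Sequence[DilutionMeasurement],
    limits: dict[str, LimitEstimates],
) -> dict[str, GroupSensitivity]:
    """Lowest positive dilution and its mean measured MAF per detection group.

    A dilution is positive when at least two replicates reach the group's
    LOD95 droplet count; the sensitivity is the mean measured MAF across all
    replicates of the lowest positive dilution.
    """
    out: dict[str, GroupSensitivity] = {}
    by_group: dict[str, list[DilutionMeasurement]] = {}
    for m in measurements:
        by_group.setdefault(m.group, []).append(m)
    for group, ms in by_group.items():
        if group not in limits:
            raise KeyError(f"no limits for group {group!r}")
        lod = limits[group].lod95_droplets
        per: dict[float, list[DilutionMeasurement]] = {}
        for m in ms:
            per.setdefault(m.theoretical_maf_pct, []).append(m)
        positive_levels = [
            maf for maf, reps in per.items()
            if sum(r.positive_droplets >= lod for r in reps) >= 2
        ]
        sens = GroupSensitivity(
            group=group,
            per_dilution_mafs={
                maf: [r.measured_maf_pct for r in reps] for maf, reps in per.items()
            },
            detected=bool(positive_levels),
        )
        if positive_levels:
            lowest = min(positive_levels)
            sens.lowest_positive_maf_pct = lowest
            sens.sensitivity_pct = float(np.mean(sens.per_dilution_mafs[lowest]))
        out[group] = sens
    return out


# ---------------------------------------------------------------------------
# cohort summaries
# ---------------------------------------------------------------------------


@dataclass
class CohortSummary:
    n_patients: int
    n_samples: int
    n_positive_patients: int
    prevalence_pct: float
    prevalence_by_histology: dict[str, float]
    mutation_counts: dict[str, int]
    relative_frequencies_pct: dict[str, float]
    copies_per_ml_stats: dict[str, tuple[float, float, float]]  # median, min, max
    maf_pct_stats: dict[str, tuple[float, float, float]]
    concordance: tuple[int, int, float]  # agree, tested, %
    median_cfdna_ng_per_ml: float
    histology_counts: dict[str, int] = field(default_factory=dict)


def _is_tested(cell) -> bool:
    return not (cell is None or (isinstance(cell, float) and np.isnan(cell)))


def cohort_summary(table: pd.DataFrame) -> CohortSummary:
    """Cohort-level prevalence, mutation spectrum and tissue concordance.

    Prevalence denominators are patients; frequency denominators are mutation
    events (a patient with two mutations counts once in prevalence, twice in
    the spectrum).  A matched pair is concordant when every plasma mutation of
    the patient is found in tissue.
    """
    missing = set(COHORT_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    if table.duplicated(subset=["patient_id", "sample_index"]).any():
        raise ValueError("duplicate (patient_id, sample_index) keys")

    patients = table.groupby("patient_id", sort=False)
    n_patients = patients.ngroups
    n_samples = len(table)

    events: dict[tuple[str, str], tuple[float, float]] = {}
    plasma_by_patient: dict[str, set[str]] = {}
    hist_by_patient: dict[str, str] = {}
    tissue_by_patient: dict[str, set[str] | None] = {}
    for pid, sub in patients:
        muts: set[str] = set()
        tissue: set[str] | None = None
        for _, row in sub.iterrows():
            for name, cp, maf in parse_mutations(row["mutations"]):
                muts.add(name)
                prev = events.get((pid, name))
                if prev is None or cp > prev[0]:
                    events[(pid, name)] = (cp, maf)
            cell = row["tissue_mutations"]
            if _is_tested(cell):
                tissue = (tissue or set()) | {n for n, _, _ in parse_mutations(cell)}
        plasma_by_patient[pid] = muts
        hist_by_patient[pid] = sub["histology"].iloc[0]
        tissue_by_patient[pid] = tissue

    positive = {p for p, m in plasma_by_patient.items() if m}
    prevalence = round_half_away(100.0 * len(positive) / n_patients, 1)

    hist_counts: dict[str, int] = {}
    hist_pos: dict[str, int] = {}
    for p, h in hist_by_patient.items():
        hist_counts[h] = hist_counts.get(h, 0) + 1
        if p in positive:
            hist_pos[h] = hist_pos.get(h, 0) + 1
    prev_by_hist = {
        h: round_half_away(100.0 * hist_pos.get(h, 0) / n, 1) for h, n in hist_counts.items()
    }
    ilc = [h for h in hist_counts if "ILC" in h]
    if ilc:
        n_ilc = sum(hist_counts[h] for h in ilc)
        prev_by_hist["ILC (pure+mixed)"] = round_half_away(
            100.0 * sum(hist_pos.get(h, 0) for h in ilc) / n_ilc, 1
        )

    mut_counts: dict[str, int] = {}
    for (_, name) in events:
        mut_counts[name] = mut_counts.get(name, 0) + 1
    total_events = sum(mut_counts.values())
    rel_freq = {
        m: round_half_away(100.0 * c / total_events, 2) for m, c in mut_counts.items()
    } if total_events else {}

    cp_stats: dict[str, tuple[float, float, float]] = {}
    maf_stats: dict[str, tuple[float, float, float]] = {}
    for m in mut_counts:
        cps = [v[0] for (pid, name), v in events.items() if name == m]
        mafs = [v[1] for (pid, name), v in events.items() if name == m]
        cp_stats[m] = (float(np.median(cps)), float(min(cps)), float(max(cps)))
        maf_stats[m] = (float(np.median(mafs)), float(min(mafs)), float(max(mafs)))

    tested = {p: t for p, t in tissue_by_patient.items() if t is not None and plasma_by_patient[p]}
    n_tested = len(tested)
    n_agree = sum(plasma_by_patient[p] <= t for p, t in tested.items())
    conc_pct = round_half_away(100.0 * n_agree / n_tested, 0) if n_tested else float("nan")

    return CohortSummary(
        n_patients=n_patients,
        n_samples=n_samples,
        n_positive_patients=len(positive),
        prevalence_pct=prevalence,
        prevalence_by_histology=prev_by_hist,
        mutation_counts=mut_counts,
        relative_frequencies_pct=rel_freq,
        copies_per_ml_stats=cp_stats,
        maf_pct_stats=maf_stats,
        concordance=(n_agree, n_tested, conc_pct),
        median_cfdna_ng_per_ml=float(table["cfdna_ng_per_ml"].median()),
        histology_counts=hist_counts,
    )
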