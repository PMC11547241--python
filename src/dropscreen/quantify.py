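"""Poisson quantification: cluster counts -> copies/PCR, copies/mL plasma, MAF.

Standard dPCR statistics: with k positive droplets among N partitions of
volume v from a reaction of volume V, the per-droplet mean occupancy is
lambda = -ln(1 - k/N) and the whole-reaction load is lambda * V / v (the
partitioned fraction N*v/V of the reaction is what is actually read, but
concentrations refer to the full reaction, matching the 10,000 copies/PCR
input cap).

For drop-off mutant targets the naive estimator is biased low: a droplet
holding both wild type and a mutant fires the drop-off probe and is counted
wild type (masking).  The conditional estimator works on the WT-negative
subpopulation, where mutant occupancy is observable, and is unbiased because
species occupancies are independent Poisson:

    lambda_mut = -ln(n_double_negative / n_WT_negative)
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from .assay import GROUP_DUP, GROUP_WT
from .gating import ClusterCounts
from .limits import corrected_blank_mean
from .simulate import NL_PER_UL, BlankPanel


@dataclass
class SamplePrep:
    """Volumes linking a PCR back to the plasma it came from."""

    plasma_volume_ml: float
    eluate_volume_ul: float = 50.0
    input_volume_ul: float = 15.0
    reaction_volume_ul: float = 25.0
    dilution_factor: float = 1.0

    def __post_init__(self) -> None:
        if min(self.plasma_volume_ml, self.eluate_volume_ul, self.input_volume_ul,
               self.reaction_volume_ul) <= 0:
            raise ValueError("all prep volumes must be > 0")
        if self.dilution_factor < 1:
            raise ValueError("dilution_factor must be >= 1")


@dataclass
class QuantResult:
    target: str
    positive_droplets: float          # k actually used (possibly LOB-corrected)
    lambda_per_droplet: float
    copies_per_pcr: float
    ci95: tuple[float, float]         # on copies_per_pcr
    copies_per_ml: float | None = None
    maf_pct: float | None = None
    mode: str = "naive"


class SaturationError(ValueError):
    """All informative partitions positive; the sample must be diluted."""


def _lambda_ci(k: float, n: float, z: float = 1.959964) -> tuple[float, float, float]:
    """Point estimate and normal CI for lambda from k positives among n."""
    p = k / n
    lam = -math.log1p(-p)
    if k > 0:
        var = p / (n * (1.0 - p))
        sd = math.sqrt(var)
        lo, hi = max(0.0, lam - z * sd), lam + z * sd
    else:
        # one-sided exact bound at 95%: lambda such that P(k=0) = 0.05
        lo, hi = 0.0, -math.log(0.05) / n
    return lam, lo, hi


def concentration_from_counts(
    counts: ClusterCounts,
    target: str,
    mode: str = "naive",
    k_override: float | None = None,
) -> QuantResult:
    """Estimate the whole-reaction template load of one detection class.

    ``mode='conditional'`` (for the drop-off hotspot class) conditions on the
    WT-negative droplet subpopulation, correcting co-occupancy masking; it
    needs the WT (and, if present, dup) tallies in ``counts`` — apply the
    dup/WT overlap correction first.  ``k_override`` substitutes an
    LOB-corrected (possibly fractional) positive-droplet count for the raw
    tally.
    """
    n = counts.total_partitions
    k = counts.counts[target] if k_override is None else k_override
    if k < 0:
        raise ValueError("positive droplet count must be >= 0")
    scale = counts.reaction_volume_ul * NL_PER_UL / counts.droplet_volume_nl

    if mode == "naive":
        if k > n:
            raise ValueError(f"data integrity: k={k} exceeds partitions N={n}")
        if k == n:
            raise SaturationError("every partition positive; dilute the sample and rerun")
        lam, lo, hi = _lambda_ci(k, n)
    elif mode == "conditional":
        wt_like = counts.counts.get(GROUP_WT, 0) + counts.counts.get(GROUP_DUP, 0)
        n_wt_neg = n - wt_like
        if k > n_wt_neg:
            raise ValueError(
                f"data integrity: k={k} exceeds WT-negative droplets {n_wt_neg}"
            )
        if k == n_wt_neg:
            raise SaturationError(
                "every WT-negative partition is mutant-positive; dilute and rerun"
            )
        lam, lo, hi = _lambda_ci(k, n_wt_neg)
    else:
        raise ValueError(f"unknown mode {mode!r}; use 'naive' or 'conditional'")

    return QuantResult(
        target=target,
        positive_droplets=float(k),
        lambda_per_droplet=lam,
        copies_per_pcr=lam * scale,
        ci95=(lo * scale, hi * scale),
        mode=mode,
    )


def concentration_ci_exact(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Clopper-Pearson interval on lambda (per-droplet), offered as an option."""
    alpha = 1 - level
    if k == 0:
        p_lo = 0.0
    else:
        p_lo = stats.beta.ppf(alpha / 2, k, n - k + 1)
    p_hi = stats.beta.ppf(1 - alpha / 2, k + 1, n - k) if k < n else 1.0
    lo = -math.log1p(-p_lo)
    hi = float("inf") if p_hi >= 1 else -math.log1p(-p_hi)
    return lo, hi


def lob_correct_counts(k: float, group: str, blanks: BlankPanel) -> float:
    """Subtract the group's corrected blank mean from a positive-droplet count.

    The corrected mean mu_corr = mu + 1.645*sigma/sqrt(N) accounts for the
    expected false-positive droplets in a blank chamber; counts are floored at
    zero and may be fractional after correction.
    """
    if group not in blanks.counts:
        raise KeyError(
            f"blank panel has no counts for group {group!r}; has {sorted(blanks.counts)}"
        )
    mu_corr = corrected_blank_mean(blanks.counts[group])
    return max(0.0, k - mu_corr)


def compute_maf(mut_copies: float, wt_copies: float) -> float:
    """Mutant allelic frequency in percent: 100 * mut / (mut + wt)."""
    if mut_copies < 0 or wt_copies < 0:
        raise ValueError("copy numbers must be >= 0")
    total = mut_copies + wt_copies
    if total == 0:
        raise ValueError("MAF undefined: mutant and wild-type copies both zero")
    return min(100.0, max(0.0, 100.0 * mut_copies / total))


def copies_per_ml_plasma(q: QuantResult, prep: SamplePrep) -> float:
    """Convert a whole-reaction load to copies per mL of plasma.

    The PCR received input_volume of the (possibly diluted) eluate; the whole
    eluate derives from plasma_volume of plasma.
    """
    factor = prep.dilution_factor * (prep.eluate_volume_ul / prep.input_volume_ul)
    return q.copies_per_pcr * factor / prep.plasma_volume_ml


def pool_replicates(replicates: list[ClusterCounts]) -> ClusterCounts:
    """Sum counts and partitions over replicate chambers of the same assay."""
    if not replicates:
        raise ValueError("nothing to pool")
    first = replicates[0]
    if len(replicates) == 1:
        return first
    assays = {c.assay for c in replicates}
    if len(assays) > 1:
        raise ValueError(f"cannot pool chambers from different assays: {sorted(assays)}")
    classes = {cls for c in replicates for cls in c.counts}
    return ClusterCounts(
        chamber_id="+".join(c.chamber_id for c in replicates),
        assay=first.assay,
        total_partitions=sum(c.total_partitions for c in replicates),
        counts={cls: sum(c.counts.get(cls, 0) for c in replicates) for cls in classes},
        unclassified=sum(c.unclassified for c in replicates),
        empty=sum(c.empty for c in replicates),
        n_multi=sum(c.n_multi for c in replicates),
        droplet_volume_nl=first.droplet_volume_nl,
        reaction_volume_ul=first.reaction_volume_ul,
        provenance_ids=tuple(pid for c in replicates for pid in c.provenance_ids),
    )
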