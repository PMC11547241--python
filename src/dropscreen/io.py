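"""File formats: droplet CSV, gate JSON, blank CSV, limits JSON, results TSV."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .gating import ClusterCounts, Gate, GateSet
from .limits import LimitEstimates
from .quantify import QuantResult
from .simulate import BlankPanel, DropletSet

QUANT_COLUMNS = (
    "target", "k_raw", "k_corrected", "lambda", "copies_per_pcr",
    "copies_per_ml", "maf_pct", "ci_low", "ci_high",
)


def droplets_to_csv(ds: DropletSet, path, provenance_path=None) -> None:
    df = ds.intensities.copy()
    df.insert(0, "droplet_id", np.arange(len(df)))
    df.insert(0, "chamber_id", ds.chamber_id)
    df.to_csv(path, index=False)
    if provenance_path is not None and ds.provenance is not None:
        ds.provenance.to_csv(provenance_path, index=False)


def droplets_from_csv(
    path,
    assay: str = "",
    droplet_volume_nl: float = 0.68,
    reaction_volume_ul: float = 25.0,
    provenance_path=None,
) -> DropletSet:
    df = pd.read_csv(path)
    required = {"chamber_id", "fam", "hex", "cy5"}
    if not required <= set(df.columns):
        raise ValueError(f"droplet CSV must have columns {sorted(required)}")
    prov = pd.read_csv(provenance_path) if provenance_path else None
    return DropletSet(
        chamber_id=str(df["chamber_id"].iloc[0]),
        assay=assay,
        n_partitions=len(df),
        droplet_volume_nl=droplet_volume_nl,
        reaction_volume_ul=reaction_volume_ul,
        intensities=df[["fam", "hex", "cy5"]].reset_index(drop=True),
        provenance=prov,
    )


def gates_to_json(gates: GateSet, path) -> None:
    obj = {
        "assay": gates.assay,
        "precedence": gates.precedence,
        "empty_thresholds": gates.empty_thresholds,
        "gates": [
            {
                "name": g.name,
                "classes": list(g.classes),
                "plane": list(g.plane),
                "vertices": [list(v) for v in g.vertices],
            }
            for g in gates.gates
        ],
    }
    Path(path).write_text(json.dumps(obj, indent=2))


def gates_from_json(path) -> GateSet:
    obj = json.loads(Path(path).read_text())
    return GateSet(
        gates=[
            Gate(
                name=g["name"],
                classes=tuple(g["classes"]),
                plane=tuple(g["plane"]),
                vertices=[tuple(v) for v in g["vertices"]],
            )
            for g in obj["gates"]
        ],
        precedence=list(obj["precedence"]),
        empty_thresholds=dict(obj["empty_thresholds"]),
        assay=obj.get("assay", ""),
    )


def counts_to_csv(counts: list[ClusterCounts], path) -> None:
    rows = []
    for cc in counts:
        for cls, k in cc.counts.items():
            rows.append(
                {
                    "chamber_id": cc.chamber_id,
                    "assay": cc.assay,
                    "total_partitions": cc.total_partitions,
                    "detection_class": cls,
                    "count": k,
                    "unclassified": cc.unclassified,
                    "empty": cc.empty,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def counts_from_csv(path) -> list[ClusterCounts]:
    df = pd.read_csv(path)
    out = []
    for (cid, assay, total), sub in df.groupby(
        ["chamber_id", "assay", "total_partitions"], sort=False
    ):
        out.append(
            ClusterCounts(
                chamber_id=str(cid),
                assay=str(assay),
                total_partitions=int(total),
                counts={r["detection_class"]: int(r["count"]) for _, r in sub.iterrows()},
                unclassified=int(sub["unclassified"].iloc[0]),
                empty=int(sub["empty"].iloc[0]),
            )
        )
    return out


def blanks_to_csv(panel: BlankPanel, path) -> None:
    rows = [
        {"group": g, "replicate": i, "count": int(c)}
        for g, arr in panel.counts.items()
        for i, c in enumerate(arr)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def blanks_from_csv(path, background_copies_per_pcr: float = 10_000.0) -> BlankPanel:
    df = pd.read_csv(path)
    counts = {
        str(g): sub.sort_values("replicate")["count"].to_numpy(dtype=int)
        for g, sub in df.groupby("group", sort=False)
    }
    n = len(next(iter(counts.values())))
    return BlankPanel(counts=counts, n_replicates=n,
                      background_copies_per_pcr=background_copies_per_pcr)


def limits_to_json(limits: dict[str, LimitEstimates], path) -> None:
    Path(path).write_text(json.dumps({g: vars(l) for g, l in limits.items()}, indent=2))


def limits_from_json(path) -> dict[str, LimitEstimates]:
    obj = json.loads(Path(path).read_text())
    return {g: LimitEstimates(**d) for g, d in obj.items()}


def quant_results_to_tsv(results: list[tuple[float, QuantResult]], path) -> None:
    """Fixed-column TSV; each row is (raw droplet count, QuantResult)."""
    rows = []
    for k_raw, q in results:
        rows.append(
            {
                "target": q.target,
                "k_raw": k_raw,
                "k_corrected": q.positive_droplets,
                "lambda": q.lambda_per_droplet,
                "copies_per_pcr": q.copies_per_pcr,
                "copies_per_ml": q.copies_per_ml,
                "maf_pct": q.maf_pct,
                "ci_low": q.ci95[0],
                "ci_high": q.ci95[1],
            }
        )
    pd.DataFrame(rows, columns=list(QUANT_COLUMNS)).to_csv(path, sep="\t", index=False)
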