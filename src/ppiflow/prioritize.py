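"""Ranking drug targets by their solved flow and lifting the ranking to drugs.

A target's score is the flow it pushes toward the risk genes (the flow on
its source arc). Drugs are scored through their targets: by default a drug
inherits the flow value of its best-ranked target, which matches output
tables that list a single target and flow value per drug. Alternative
aggregations (sum, mean over a drug's mapped targets) are available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

from .io import DrugTargetMap

log = logging.getLogger(__name__)

DRUG_AGGREGATIONS = ("max", "sum", "mean")


@dataclass(frozen=True)
class TargetRanking:
    """Targets ordered by non-increasing flow; ties broken by node ID."""

    entries: tuple[tuple[str, float], ...]

    def as_dict(self) -> dict[str, float]:
        return dict(self.entries)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class DrugRanking:
    """Drugs ordered by non-increasing score; each entry is (drug, score, best_target)."""

    entries: tuple[tuple[str, float, str], ...]

    def top(self, k: int) -> tuple[tuple[str, float, str], ...]:
        return self.entries[: max(k, 0)]

    def __len__(self) -> int:
        return len(self.entries)


def rank_targets(outflows: dict[str, float]) -> TargetRanking:
    """Sort targets by descending flow; ties broken lexicographically by ID."""
    if not outflows:
        raise ValueError("no target outflows to rank")
    entries = tuple(sorted(outflows.items(), key=lambda kv: (-kv[1], kv[0])))
    return TargetRanking(entries=entries)


def rank_drugs(tr: TargetRanking, dti: DrugTargetMap, agg: str = "max") -> DrugRanking:
    """Score each drug through its targets present in the ranking.

    A drug whose targets are all absent from the ranking is dropped (with a
    logged count): only ranked targets receive source arcs, so other
    interactions carry no flow information. ``best_target`` is the mapped
    target with the highest flow (ties to the lexicographically smallest ID).
    """
    if agg not in DRUG_AGGREGATIONS:
        raise ValueError(f"agg must be one of {DRUG_AGGREGATIONS}")
    if not dti.pairs:
        raise ValueError("empty drug-target map")
    flows = tr.as_dict()
    scored: list[tuple[str, float, str]] = []
    n_dropped = 0
    for drug, targets in sorted(dti.by_drug().items()):
        mapped = sorted(t for t in targets if t in flows)
        if not mapped:
            n_dropped += 1
            continue
        best = min(mapped, key=lambda t: (-flows[t], t))
        values = [flows[t] for t in mapped]
        if agg == "max":
            score = flows[best]
        elif agg == "sum":
            score = sum(values)
        else:
            score = sum(values) / len(values)
        scored.append((drug, score, best))
    if n_dropped:
        log.info("dropped %d drug(s) with no ranked target", n_dropped)
    if not scored:
        raise ValueError("no drug has a target in the ranking")
    scored.sort(key=lambda e: (-e[1], e[0]))
    return DrugRanking(entries=tuple(scored))


def write_target_ranking(tr: TargetRanking, path: str | Path, total_flow: float | None = None) -> None:
    """Write the target ranking as TSV: target_id, flow_value, [flow_fraction,] rank."""
    with open(path, "w", encoding="utf-8") as fh:
        if total_flow:
            fh.write("target_id\tflow_value\tflow_fraction\trank\n")
            for rank, (t, f) in enumerate(tr.entries, start=1):
                fh.write(f"{t}\t{f:.8g}\t{f / total_flow:.8g}\t{rank}\n")
        else:
            fh.write("target_id\tflow_value\trank\n")
            for rank, (t, f) in enumerate(tr.entries, start=1):
                fh.write(f"{t}\t{f:.8g}\t{rank}\n")


def report(
    tr: TargetRanking,
    dr: DrugRanking,
    k: int,
    path: str | Path,
    total_flow: float | None = None,
) -> None:
    """Write the top-k drug report as TSV.

    Columns: drug_id, best_target, flow_value, flow_fraction (share of the
    total flow, when known) and rank. Flow values are reported both raw and
    as a fraction of total flow because either convention is a defensible
    per-target score.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("drug_id\tbest_target\tflow_value\tflow_fraction\trank\n")
        for rank, (drug, score, best) in enumerate(dr.top(k), start=1):
            frac = score / total_flow if total_flow else float("nan")
            fh.write(f"{drug}\t{best}\t{score:.8g}\t{frac:.8g}\t{rank}\n")
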