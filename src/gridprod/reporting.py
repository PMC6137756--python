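"""Run reports: JSON/TSV serialization of design results."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

from .grid_search import GridConfig, GridProdResult, is_producible

__all__ = ["RunReport", "report_from_result", "cells_to_tsv"]


@dataclass(frozen=True)
class RunReport:
    """Flat, serializable summary of one design run."""

    target_id: str
    tmgr: float
    tmpr: float
    best_cell: tuple[int, int]
    pr: float
    pr_fva_min: float
    pr_fva_max: float
    knockouts: tuple[str, ...]
    reactions_used: int
    producible_fva_min: bool
    producible_fva_max: bool
    elapsed_seconds: float

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunReport":
        raw = json.loads(text)
        raw["best_cell"] = tuple(raw["best_cell"])
        raw["knockouts"] = tuple(raw["knockouts"])
        return cls(**raw)


def report_from_result(target_id: str, result: GridProdResult,
                       config: GridConfig, elapsed_seconds: float) -> RunReport:
    return RunReport(
        target_id=target_id,
        tmgr=result.tmgr,
        tmpr=result.tmpr,
        best_cell=result.best_cell,
        pr=result.pr,
        pr_fva_min=result.pr_fva_min,
        pr_fva_max=result.pr_fva_max,
        knockouts=tuple(sorted(result.knockouts)),
        reactions_used=result.reactions_used,
        producible_fva_min=is_producible(result, "fva_min", config),
        producible_fva_max=is_producible(result, "fva_max", config),
        elapsed_seconds=elapsed_seconds,
    )


def cells_to_tsv(result: GridProdResult, path: str | Path) -> None:
    """Dump the per-cell trace as a diff-able TSV."""
    header = ["i", "j", "gr_lower", "gr_upper", "pr_lower", "pr_upper",
              "status", "n_knockouts", "gr", "pr_stored"]
    lines = ["\t".join(header)]
    for res in result.cells:
        c = res.cell
        lines.append("\t".join(str(x) for x in [
            c.i, c.j, f"{c.gr_lower:.6g}", f"{c.gr_upper:.6g}",
            f"{c.pr_lower:.6g}", f"{c.pr_upper:.6g}", res.first_lp_status,
            len(res.knockout_set), f"{res.second_lp_gr:.6g}",
            f"{res.stored_pr:.6g}",
        ]))
    Path(path).write_text("\n".join(lines) + "\n")
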