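"""Stage summaries and the machine-readable cascade report."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

from .annotate import round_half_up
from .intervals import CascadeResult
from .regions import DirectedRegionSet

__all__ = ["SummaryTable", "summarize", "summarize_counts", "render_report", "write_report"]


@dataclass(frozen=True)
class SummaryTable:
    """Hyper/hypo counts and percentages for one region set.

    Percentages are rounded half-up to 2 decimals (printed-table
    style); the raw fractions are kept alongside.  An empty set reports
    counts of 0 and empty (None) percentages.
    """

    name: str
    n_total: int
    n_hyper: int
    n_hypo: int
    pct_hyper: float | None
    pct_hypo: float | None
    frac_hyper: float | None
    frac_hypo: float | None
    conflicts_eliminated: int = 0


def summarize_counts(
    name: str, n_hyper: int, n_hypo: int, conflicts: int = 0
) -> SummaryTable:
    """Summary arithmetic from raw hyper/hypo counts."""
    n_total = n_hyper + n_hypo
    if n_total == 0:
        return SummaryTable(name, 0, 0, 0, None, None, None, None, conflicts)
    fh = n_hyper / n_total
    fl = n_hypo / n_total
    return SummaryTable(
        name=name,
        n_total=n_total,
        n_hyper=n_hyper,
        n_hypo=n_hypo,
        pct_hyper=round_half_up(100.0 * fh),
        pct_hypo=round_half_up(100.0 * fl),
        frac_hyper=fh,
        frac_hypo=fl,
        conflicts_eliminated=conflicts,
    )


def summarize(rs: DirectedRegionSet, conflicts: int = 0) -> SummaryTable:
    return summarize_counts(rs.name, rs.n_hyper, rs.n_hypo, conflicts)


def render_report(cascade: CascadeResult, seed: int | None = None) -> dict:
    """One JSON-able object with all stage summaries and provenance.

    Key order is stable (stage order, then per-stage fields) so equal
    runs produce byte-identical serialized reports.
    """
    stages = {}
    for name in ("DMR1", "DMR2", "DMR3", "DMR4", "DMR5", "DMR6", "DMR7"):
        rs = cascade.sets[name]
        table = summarize(rs, cascade.eliminated_opposite.get(name, 0))
        d = asdict(table)
        d["provenance"] = rs.provenance
        stages[name] = d
    return {
        "parameters": {
            "max_gap": cascade.params.max_gap,
            "min_cpgs": cascade.params.min_cpgs,
            "min_diff": cascade.params.min_diff,
            "min_coverage": cascade.params.min_coverage,
            "alpha": cascade.params.alpha,
        },
        "seed": seed,
        "stages": stages,
        "eliminated_opposite": dict(cascade.eliminated_opposite),
        "dmr7_hyper_selected": len(cascade.dmr7_hyper),
    }


def write_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=False)
        fh.write("\n")
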