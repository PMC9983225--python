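"""Direction-aware genomic interval set algebra and the DMR1->DMR7 cascade.

All operations use bedtools-style semantics: overlap means >= 1 bp
shared under 0-based half-open arithmetic, and intersections report the
query set's original intervals (``-wa``), deduplicated, so an output
region always keeps its own coordinates, delta and direction.

The cascade nominates decitabine-responsive regions specific to
t(8;21) AML:

* DMR1 — t(8;21) vs non-t(8;21) de novo patients;
* DMR2 — AML1-ETO-positive vs -silenced cell line pair;
* DMR3 — same-direction overlap of DMR1 with DMR2 (the
  translocation-associated signature);
* DMR4 / DMR5 — treatment-responsive regions recurring with a common
  direction across the t(8;21) / non-t(8;21) de novo-vs-remission pairs
  (delta = de novo minus CR, so "hyper" means methylation was reduced
  by treatment);
* DMR6 — DMR4 regions with no same-direction DMR5 overlap (responses
  specific to t(8;21));
* DMR7 — same-direction overlap of DMR3 with DMR6; opposite-direction
  overlaps are eliminated and counted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calling import DmrParams, call_dmrs
from .io import MethylationMatrix
from .regions import DMR, HYPER, HYPO, DirectedRegionSet, classify_direction

log = logging.getLogger(__name__)

__all__ = [
    "classify_direction",
    "intersect_directed",
    "subtract_unique",
    "recurrent_consistent",
    "CascadeResult",
    "run_cascade",
]


def _merged_intervals(regions) -> dict:
    """Per-chromosome disjoint union of intervals, as sorted arrays."""
    by_chrom: dict[str, list] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
    out = {}
    for chrom, ivals in by_chrom.items():
        ivals.sort()
        starts, ends = [], []
        for s, e in ivals:
            if ends and s <= ends[-1]:
                ends[-1] = max(ends[-1], e)
            else:
                starts.append(s)
                ends.append(e)
        out[chrom] = (np.asarray(starts), np.asarray(ends))
    return out


def _overlaps_any(merged: dict, region: DMR) -> bool:
    if region.chrom not in merged:
        return False
    starts, ends = merged[region.chrom]
    # rightmost merged interval with start < region.end
    i = int(np.searchsorted(starts, region.end, side="left")) - 1
    return i >= 0 and ends[i] > region.start


def intersect_directed(
    a: DirectedRegionSet, b: DirectedRegionSet, mode: str, name: str = ""
) -> DirectedRegionSet:
    """Regions of ``a`` overlapping a ``b`` region of matching direction.

    ``mode="same"`` requires an equal direction, ``mode="opposite"`` a
    differing one.  Output keeps ``a``'s coordinates, delta and
    direction (-wa semantics); a region overlapping several ``b``
    partners is emitted once.
    """
    if mode not in ("same", "opposite"):
        raise ValueError(f"mode must be 'same' or 'opposite', got {mode!r}")
    merged = {
        d: _merged_intervals(r for r in b.regions if r.direction == d)
        for d in (HYPER, HYPO)
    }
    hits = []
    for r in a.regions:
        want = (
            r.direction
            if mode == "same"
            else (HYPO if r.direction == HYPER else HYPER)
        )
        if _overlaps_any(merged[want], r):
            hits.append(r)
    return DirectedRegionSet(
        name=name or f"{a.name}&{b.name}[{mode}]",
        regions=hits,
        provenance=f"intersect_directed({a.name}, {b.name}, {mode})",
    )


def subtract_unique(
    a: DirectedRegionSet, b: DirectedRegionSet, name: str = ""
) -> DirectedRegionSet:
    """Regions of ``a`` with no same-direction overlap in ``b``.

    The complement of ``intersect_directed(a, b, "same")`` within
    ``a``.  Regions retained although they overlap an
    opposite-direction ``b`` region are flagged in ``conflicts``.
    """
    same = {r.sort_key() + (r.direction,) for r in intersect_directed(a, b, "same")}
    opposite = {
        r.sort_key() + (r.direction,) for r in intersect_directed(a, b, "opposite")
    }
    kept = [r for r in a.regions if r.sort_key() + (r.direction,) not in same]
    flagged = [
        r for r in kept if r.sort_key() + (r.direction,) in opposite
    ]
    return DirectedRegionSet(
        name=name or f"{a.name}-{b.name}",
        regions=kept,
        provenance=f"subtract_unique({a.name}, {b.name})",
        conflicts=flagged,
    )


def recurrent_consistent(
    per_unit_sets: list[DirectedRegionSet], name: str = ""
) -> DirectedRegionSet:
    """Regions recurring with one direction across every unit set.

    Returns regions of the first unit set that overlap, in each other
    unit, at least one region of the same direction; coordinates come
    from the first set (-wa convention).  First-set regions overlapping
    an opposite-direction region in any unit are recorded as conflicts
    (they may still qualify; the conflict is reported either way).
    """
    if len(per_unit_sets) < 2:
        raise ValueError("recurrent_consistent needs >= 2 unit sets")
    anchor = per_unit_sets[0]
    result = anchor
    for other in per_unit_sets[1:]:
        result = intersect_directed(result, other, "same")
    conflict_keys: set = set()
    for other in per_unit_sets[1:]:
        for r in intersect_directed(anchor, other, "opposite"):
            conflict_keys.add(r.sort_key() + (r.direction,))
    conflicts = [
        r for r in anchor.regions if r.sort_key() + (r.direction,) in conflict_keys
    ]
    return DirectedRegionSet(
        name=name or f"recurrent({anchor.name})",
        regions=result.regions,
        provenance=f"recurrent_consistent({[s.name for s in per_unit_sets]})",
        conflicts=conflicts,
    )


@dataclass
class CohortRoles:
    """Sample-sheet roles the cascade needs.

    group column values: ``t821`` / ``non_t821`` for patients,
    ``cellline`` for the AML1-ETO cell line pair; timepoint values:
    ``de_novo`` / ``cr`` for patients, ``ae_pos`` / ``ae_neg`` for the
    cell lines.  Paired samples share a ``pair_id``.
    """

    t821_de_novo: list[str]
    non_t821_de_novo: list[str]
    cell_ae_pos: str
    cell_ae_neg: str
    t821_pairs: list[tuple[str, str]]  # (de novo, CR)
    non_t821_pairs: list[tuple[str, str]]

    @classmethod
    def from_sample_sheet(cls, samples: pd.DataFrame) -> "CohortRoles":
        def pick(**kw):
            m = np.ones(len(samples), dtype=bool)
            for col, val in kw.items():
                m &= samples[col].to_numpy() == val
            return list(samples.loc[m, "sample_id"])

        def pairs(group):
            out = []
            sub = samples[
                (samples["group"] == group) & (samples["pair_id"] != "")
            ]
            for pid, grp in sub.groupby("pair_id"):
                dn = grp.loc[grp["timepoint"] == "de_novo", "sample_id"]
                cr = grp.loc[grp["timepoint"] == "cr", "sample_id"]
                if len(dn) != 1 or len(cr) != 1:
                    raise ValueError(
                        f"pair {pid!r} must have one de_novo and one cr sample"
                    )
                out.append((dn.iloc[0], cr.iloc[0]))
            return sorted(out)

        ae_pos = pick(group="cellline", timepoint="ae_pos")
        ae_neg = pick(group="cellline", timepoint="ae_neg")
        roles = cls(
            t821_de_novo=pick(group="t821", timepoint="de_novo"),
            non_t821_de_novo=pick(group="non_t821", timepoint="de_novo"),
            cell_ae_pos=ae_pos[0] if ae_pos else "",
            cell_ae_neg=ae_neg[0] if ae_neg else "",
            t821_pairs=pairs("t821"),
            non_t821_pairs=pairs("non_t821"),
        )
        roles.validate()
        return roles

    def validate(self) -> None:
        missing = []
        if not self.t821_de_novo:
            missing.append("t(8;21) de novo samples")
        if not self.non_t821_de_novo:
            missing.append("non-t(8;21) de novo samples")
        if not (self.cell_ae_pos and self.cell_ae_neg):
            missing.append("AML1-ETO cell line pair")
        if len(self.t821_pairs) < 2:
            missing.append(">=2 t(8;21) de novo/CR pairs")
        if len(self.non_t821_pairs) < 2:
            missing.append(">=2 non-t(8;21) de novo/CR pairs")
        if missing:
            raise ValueError(f"cohort is missing: {', '.join(missing)}")


@dataclass
class CascadeResult:
    """The seven named region sets plus per-stage provenance counts."""

    sets: dict
    stage_counts: dict = field(default_factory=dict)
    eliminated_opposite: dict = field(default_factory=dict)
    params: DmrParams = field(default_factory=DmrParams)

    @property
    def dmr7_hyper(self) -> DirectedRegionSet:
        """Hypermethylated DMR7 subset selected for promoter annotation."""
        return self.sets["DMR7"].by_direction(HYPER)

    def __getitem__(self, name: str) -> DirectedRegionSet:
        return self.sets[name]


def run_cascade(
    matrix: MethylationMatrix,
    roles: CohortRoles | None = None,
    params: DmrParams = DmrParams(),
) -> CascadeResult:
    """Run the full DMR1->DMR7 construction on a cohort matrix."""
    if roles is None:
        roles = CohortRoles.from_sample_sheet(matrix.samples)
    roles.validate()

    dmr1 = DirectedRegionSet(
        "DMR1",
        call_dmrs(matrix, roles.t821_de_novo, roles.non_t821_de_novo, params),
        provenance="t(8;21) de novo vs non-t(8;21) de novo",
    )
    dmr2 = DirectedRegionSet(
        "DMR2",
        call_dmrs(matrix, [roles.cell_ae_pos], [roles.cell_ae_neg], params),
        provenance="AML1-ETO-positive vs -silenced cell line",
    )
    dmr3 = intersect_directed(dmr1, dmr2, "same", name="DMR3")
    dmr3_opposite = intersect_directed(dmr1, dmr2, "opposite", name="DMR3.opp")

    def pair_sets(pairs, label):
        return [
            DirectedRegionSet(
                f"{label}.pair{k + 1}",
                call_dmrs(matrix, [dn], [cr], params),
                provenance=f"{dn} (de novo) vs {cr} (CR)",
            )
            for k, (dn, cr) in enumerate(pairs)
        ]

    dmr4 = recurrent_consistent(pair_sets(roles.t821_pairs, "t821"), name="DMR4")
    dmr5 = recurrent_consistent(
        pair_sets(roles.non_t821_pairs, "non_t821"), name="DMR5"
    )
    dmr6 = subtract_unique(dmr4, dmr5, name="DMR6")
    dmr7 = intersect_directed(dmr3, dmr6, "same", name="DMR7")
    dmr7_keys = {r.sort_key() + (r.direction,) for r in dmr7}
    eliminated = [
        r
        for r in intersect_directed(dmr3, dmr6, "opposite")
        if r.sort_key() + (r.direction,) not in dmr7_keys
    ]

    sets = {
        "DMR1": dmr1,
        "DMR2": dmr2,
        "DMR3": dmr3,
        "DMR4": dmr4,
        "DMR5": dmr5,
        "DMR6": dmr6,
        "DMR7": dmr7,
    }
    counts = {name: len(s) for name, s in sets.items()}
    eliminated_counts = {
        "DMR3": len(dmr3_opposite),  # DMR1 regions with opposite DMR2 overlap
        "DMR4": len(dmr4.conflicts),
        "DMR5": len(dmr5.conflicts),
        "DMR6_opposite_flagged": len(dmr6.conflicts),
        "DMR7": len(eliminated),
    }
    for stage, n in counts.items():
        log.info("%s: %d regions", stage, n)
    log.info(
        "DMR7: eliminated %d opposite-direction overlaps", eliminated_counts["DMR7"]
    )
    return CascadeResult(
        sets=sets,
        stage_counts=counts,
        eliminated_opposite=eliminated_counts,
        params=params,
    )
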