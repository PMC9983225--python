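"""Genomic-category annotation of DMRs and promoter-gene mapping.

The promoter window spans 2200 bp upstream through 500 bp downstream of
the TSS in transcription orientation (2700 bp total, TSS base
included), clipped at the chromosome start.  Relative to each gene a
region is classified Promoter (overlaps only the promoter window),
GeneBody (overlaps only the transcript outside the promoter window),
or P/Gb (both); the 500 bp of promoter window that lie inside the
transcript count as promoter, which makes the categories a true
partition per gene.  Across genes the precedence is
P/Gb > Promoter > GeneBody; a region touching no gene is "Other".
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .io import GeneModel
from .regions import DMR, HYPER, HYPO, DirectedRegionSet

__all__ = [
    "PROMOTER_UPSTREAM",
    "PROMOTER_DOWNSTREAM",
    "PromoterWindow",
    "promoter_window",
    "GenomeAnnotator",
    "annotate_dmr",
    "promoter_genes",
    "distribution_table",
    "round_half_up",
]

PROMOTER_UPSTREAM = 2200
PROMOTER_DOWNSTREAM = 500

PROMOTER = "Promoter"
GENE_BODY = "GeneBody"
P_GB = "P/Gb"
OTHER = "Other"
CATEGORIES = (PROMOTER, GENE_BODY, P_GB, OTHER)


@dataclass(frozen=True)
class PromoterWindow:
    gene_id: str
    chrom: str
    start: int
    end: int


def promoter_window(
    gene: GeneModel,
    upstream: int = PROMOTER_UPSTREAM,
    downstream: int = PROMOTER_DOWNSTREAM,
) -> PromoterWindow:
    """Strand-resolved promoter window, half-open, clipped at 0.

    + strand: TSS = tx_start, window [TSS-2200, TSS+500).
    - strand: TSS = tx_end-1, window [TSS-499, TSS+2201) — the mirror
    image, so upstream lies at genomic coordinates above the TSS.
    """
    tss = gene.tss
    if gene.strand == "+":
        start, end = tss - upstream, tss + downstream
    else:
        start, end = tss - downstream + 1, tss + upstream + 1
    return PromoterWindow(gene.gene_id, gene.chrom, max(0, start), end)


def _overlap(a_start, a_end, b_start, b_end) -> bool:
    return a_start < b_end and b_start < a_end


class GenomeAnnotator:
    """Indexes gene models for repeated DMR category queries."""

    def __init__(self, genes) -> None:
        self.genes = list(genes)
        self._by_chrom: dict[str, list] = {}
        for g in self.genes:
            p = promoter_window(g)
            # reach = full extent a DMR may overlap for this gene
            lo = min(p.start, g.tx_start)
            hi = max(p.end, g.tx_end)
            self._by_chrom.setdefault(g.chrom, []).append((lo, hi, g, p))
        self._starts = {}
        for chrom, entries in self._by_chrom.items():
            entries.sort(key=lambda t: t[0])
            self._starts[chrom] = np.array([t[0] for t in entries])

    def _candidates(self, chrom, start, end):
        entries = self._by_chrom.get(chrom)
        if not entries:
            return
        starts = self._starts[chrom]
        j = int(np.searchsorted(starts, end, side="left"))
        for lo, hi, g, p in entries[:j]:
            if hi > start:
                yield g, p

    def annotate(self, dmr: DMR) -> tuple[str, list[str]]:
        """Category plus the gene ids supporting it.

        Per candidate gene: overlap with the promoter window only ->
        Promoter; with the transcript outside the promoter window only
        -> GeneBody; with both -> P/Gb.  Aggregated with precedence
        P/Gb > Promoter > GeneBody.
        """
        per_gene: dict[str, list[str]] = {P_GB: [], PROMOTER: [], GENE_BODY: []}
        for g, p in self._candidates(dmr.chrom, dmr.start, dmr.end):
            in_prom = _overlap(dmr.start, dmr.end, p.start, p.end)
            # gene body = transcript minus the promoter window
            body_parts = _interval_difference(
                g.tx_start, g.tx_end, p.start, p.end
            )
            in_body = any(
                _overlap(dmr.start, dmr.end, s, e) for s, e in body_parts
            )
            if in_prom and in_body:
                per_gene[P_GB].append(g.gene_id)
            elif in_prom:
                per_gene[PROMOTER].append(g.gene_id)
            elif in_body:
                per_gene[GENE_BODY].append(g.gene_id)
        for cat in (P_GB, PROMOTER, GENE_BODY):
            if per_gene[cat]:
                return cat, sorted(per_gene[cat])
        return OTHER, []

    def annotate_set(self, dmrs) -> pd.DataFrame:
        rows = []
        for r in dmrs:
            cat, hits = self.annotate(r)
            rows.append(
                (r.chrom, r.start, r.end, r.delta, r.direction, cat, ",".join(hits))
            )
        return pd.DataFrame(
            rows,
            columns=["chrom", "start", "end", "delta", "direction", "category", "genes"],
        )


def _interval_difference(a_start, a_end, b_start, b_end):
    """[a_start, a_end) minus [b_start, b_end), as 0-2 intervals."""
    parts = []
    if a_start < min(b_start, a_end):
        parts.append((a_start, min(b_start, a_end)))
    if max(b_end, a_start) < a_end:
        parts.append((max(b_end, a_start), a_end))
    return parts


def annotate_dmr(dmr: DMR, genes) -> tuple[str, list[str]]:
    """One-shot annotation; build a GenomeAnnotator for repeated use."""
    return GenomeAnnotator(genes).annotate(dmr)


def promoter_genes(dmrs: DirectedRegionSet, genes) -> list[str]:
    """Unique genes whose promoter window overlaps a Promoter or P/Gb DMR.

    Both classes feed the gene funnel: a P/Gb region still covers
    promoter sequence.  Gene ids are collected from the regions'
    promoter-window hits and deduplicated.
    """
    annot = GenomeAnnotator(genes)
    hit: set[str] = set()
    for r in dmrs:
        cat, _ = annot.annotate(r)
        if cat not in (PROMOTER, P_GB):
            continue
        for g, p in annot._candidates(r.chrom, r.start, r.end):
            if _overlap(r.start, r.end, p.start, p.end):
                hit.add(g.gene_id)
    return sorted(hit)


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Decimal round-half-up (printed-table style, e.g. 98.665 -> 98.67)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def distribution_table(annotated: pd.DataFrame) -> pd.DataFrame:
    """Category x direction counts with per-direction-column percentages.

    Percentages are 100*count/total per direction, rounded half-up to 2
    decimals; an empty input yields an empty table.
    """
    if len(annotated) == 0:
        return pd.DataFrame(
            columns=["category", "direction", "count", "pct"]
        )
    rows = []
    for direction in (HYPER, HYPO):
        sub = annotated[annotated["direction"] == direction]
        total = len(sub)
        if total == 0:
            continue
        counts = sub["category"].value_counts()
        for cat in CATEGORIES:
            c = int(counts.get(cat, 0))
            rows.append(
                (cat, direction, c, round_half_up(100.0 * c / total))
            )
    return pd.DataFrame(rows, columns=["category", "direction", "count", "pct"])
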