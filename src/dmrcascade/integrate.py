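"""Expression integration: a simple two-group DE stage and the
methylation x expression gene funnel.

The DE stage is deliberately plain — per-gene Welch t-test on
log-scale expression with Benjamini–Hochberg correction — because the
funnel consumes only the resulting down-regulated gene set; any
external DE backend's gene list can be substituted through
``intersect_genes``'s list input.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .regions import DMR

log = logging.getLogger(__name__)

__all__ = [
    "differential_expression",
    "intersect_genes",
    "overlap_probe_regions",
]


def differential_expression(
    expr: pd.DataFrame,
    group_a,
    group_b,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene Welch t-test between sample groups on log2 expression.

    ``expr`` is genes x samples (log scale).  Returns a DataFrame with
    gene_id, log2_fc (group_a mean minus group_b mean), p_value,
    q_value (BH) and status in {down, up, ns}; status is "down" iff
    log2_fc < 0 and q < alpha.
    """
    group_a, group_b = list(group_a), list(group_b)
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs >= 2 samples")
    a = expr[group_a].to_numpy(dtype=float)
    b = expr[group_b].to_numpy(dtype=float)
    log2_fc = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    flat = (a.std(axis=1) == 0) & (b.std(axis=1) == 0)
    if flat.any():
        log.warning("%d gene(s) with zero variance in both groups; p set to 1",
                    int(flat.sum()))
    p = np.where(flat | ~np.isfinite(p), 1.0, p)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    status = np.where(
        (q < alpha) & (log2_fc < 0),
        "down",
        np.where((q < alpha) & (log2_fc > 0), "up", "ns"),
    )
    return pd.DataFrame(
        {
            "gene_id": expr.index,
            "log2_fc": log2_fc,
            "p_value": p,
            "q_value": q,
            "status": status,
        }
    ).reset_index(drop=True)


def intersect_genes(hypermethylated_genes, de) -> pd.DataFrame:
    """Candidate genes: promoter-hypermethylated AND expression-down.

    ``de`` is either a DE result DataFrame (from
    :func:`differential_expression`) or a plain iterable of
    down-regulated gene ids.  Matching is exact (case-sensitive).
    Result is stably sorted by q_value when available, else by gene id.
    """
    hyper = set(hypermethylated_genes)
    if isinstance(de, pd.DataFrame):
        down = de[de["status"] == "down"]
        hit = down[down["gene_id"].isin(hyper)]
        hit = hit.sort_values(
            ["q_value", "gene_id"], kind="stable"
        ).reset_index(drop=True)
        return hit[["gene_id", "log2_fc", "p_value", "q_value"]]
    down_ids = sorted(hyper.intersection(de))
    return pd.DataFrame({"gene_id": down_ids})


def overlap_probe_regions(dmrs, probes: pd.DataFrame) -> pd.DataFrame:
    """Array probes overlapping >= 1 DMR (any-overlap, half-open).

    ``probes`` needs columns chrom, start, end, probe_id, gene_id
    (BED6-style with the gene in the name/extra field).  Returns the
    hit probes with their gene annotation, sorted by gene then probe.
    """
    regions = list(dmrs)
    rows = []
    for probe in probes.itertuples(index=False):
        for r in regions:
            if (
                r.chrom == probe.chrom
                and r.start < probe.end
                and probe.start < r.end
            ):
                rows.append(
                    (
                        probe.probe_id,
                        probe.gene_id,
                        probe.chrom,
                        int(probe.start),
                        int(probe.end),
                        r.start,
                        r.end,
                    )
                )
                break
    return pd.DataFrame(
        rows,
        columns=[
            "probe_id",
            "gene_id",
            "chrom",
            "start",
            "end",
            "dmr_start",
            "dmr_end",
        ],
    ).sort_values(["gene_id", "probe_id"], kind="stable").reset_index(drop=True)
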