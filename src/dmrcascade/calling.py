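"""Two-group DMR calling from per-CpG methylation levels.

The caller follows the classic segmentation recipe used by CpG-level
DMR tools: CpGs are first grouped into runs whose consecutive gaps do
not exceed ``max_gap``; within each run the per-CpG group-mean
difference profile is recursively split at the point of maximal
between-segment contrast; adjacent leaf segments whose mean difference
clears ``min_diff`` with a common sign are merged into candidate
regions; candidates with at least ``min_cpgs`` CpGs are tested with a
two-sided Mann–Whitney U of the per-CpG differences against their
negation (a zero-centered symmetric null) and Benjamini–Hochberg
adjusted across all candidates of the comparison.

Degenerate designs with a single sample on either side (de novo vs CR
of one patient, or a cell-line pair) carry no within-group replication,
so candidates are returned on the ``min_diff``/``min_cpgs`` criteria
alone with ``q_value`` reported as NaN; replication is supplied
downstream by cross-pair recurrence.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import MethylationMatrix
from .regions import DMR, classify_direction

log = logging.getLogger(__name__)

__all__ = ["DmrParams", "compute_level", "presegment", "call_dmrs"]


@dataclass(frozen=True)
class DmrParams:
    """Thresholds governing DMR calling.

    max_gap : bp — maximum distance between consecutive CpGs in a region.
    min_cpgs : minimum CpGs per region.
    min_diff : minimum absolute group mean beta difference.
    min_coverage : reads required per CpG per sample; below it the site
        is masked for that sample.
    alpha : BH q-value cutoff for tested comparisons.
    """

    max_gap: int = 300
    min_cpgs: int = 5
    min_diff: float = 0.2
    min_coverage: int = 5
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.max_gap <= 0:
            raise ValueError("max_gap must be > 0")
        if self.min_cpgs < 2:
            raise ValueError("min_cpgs must be >= 2")
        if not 0 < self.min_diff < 1:
            raise ValueError("min_diff must be in (0, 1)")


def compute_level(meth_reads, total_reads, min_coverage: int = 1):
    """Methylation level beta = methylated reads / total reads.

    Sites with ``total_reads`` below ``min_coverage`` (including zero)
    are masked to NaN rather than reported as 0.
    """
    meth = np.asarray(meth_reads, dtype=float)
    total = np.asarray(total_reads, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = meth / total
    return np.where(total >= max(1, min_coverage), beta, np.nan)


def presegment(positions, max_gap: int, min_cpgs: int = 2) -> list[tuple[int, int]]:
    """Split sorted positions into maximal runs with gaps <= max_gap.

    Returns half-open index slices ``(i, j)`` into ``positions``; runs
    with fewer than ``min_cpgs`` sites are discarded.
    """
    pos = np.asarray(positions)
    if pos.size == 0:
        return []
    if np.any(np.diff(pos) < 0):
        raise ValueError("positions must be sorted")
    breaks = np.flatnonzero(np.diff(pos) > max_gap) + 1
    bounds = np.concatenate(([0], breaks, [pos.size]))
    return [
        (int(i), int(j))
        for i, j in zip(bounds[:-1], bounds[1:])
        if j - i >= min_cpgs
    ]


def _best_split(cumsum: np.ndarray, lo: int, hi: int):
    """Best split index k in (lo, hi) of the difference profile.

    Maximizes |mean(left) - mean(right)| * sqrt(nl*nr/n), the numerator
    of a two-sample z; returns (k, weighted contrast, raw mean gap).
    """
    n = hi - lo
    ks = np.arange(lo + 1, hi)
    nl = ks - lo
    nr = hi - ks
    total = cumsum[hi] - cumsum[lo]
    left = cumsum[ks] - cumsum[lo]
    mean_l = left / nl
    mean_r = (total - left) / nr
    gap = np.abs(mean_l - mean_r)
    contrast = gap * np.sqrt(nl * nr / n)
    i = int(np.argmax(contrast))
    return int(ks[i]), float(contrast[i]), float(gap[i])


def _segment(
    cumsum: np.ndarray, lo: int, hi: int, min_gap: float, min_stat: float,
    leaves: list,
) -> None:
    """Recursive binary segmentation; appends leaf slices to ``leaves``.

    A segment splits when the best split's raw mean gap clears
    ``min_gap`` or its size-weighted contrast clears ``min_stat`` — the
    latter separates a short near-zero stretch wedged between two long
    shifted blocks, where the raw gap alone is diluted.
    """
    if hi - lo < 4:
        leaves.append((lo, hi))
        return
    k, contrast, gap = _best_split(cumsum, lo, hi)
    if gap < min_gap and contrast < min_stat:
        leaves.append((lo, hi))
        return
    _segment(cumsum, lo, k, min_gap, min_stat, leaves)
    _segment(cumsum, k, hi, min_gap, min_stat, leaves)


def _merge_leaves(d: np.ndarray, leaves: list, min_diff: float) -> list[tuple[int, int]]:
    """Merge consecutive qualifying leaves with a common sign."""
    out: list[tuple[int, int]] = []
    cur = None
    cur_sign = 0
    for lo, hi in leaves:
        m = float(np.mean(d[lo:hi]))
        sign = 1 if m >= min_diff else (-1 if m <= -min_diff else 0)
        if sign != 0 and sign == cur_sign and cur is not None and cur[1] == lo:
            cur = (cur[0], hi)
        else:
            if cur is not None and cur_sign != 0:
                out.append(cur)
            cur = (lo, hi) if sign != 0 else None
            cur_sign = sign
    if cur is not None and cur_sign != 0:
        out.append(cur)
    return out


def call_dmrs(
    matrix: MethylationMatrix,
    group_a,
    group_b,
    params: DmrParams = DmrParams(),
) -> list[DMR]:
    """Call DMRs between two sample groups.

    ``delta`` is group_a mean minus group_b mean; regions with
    ``delta > 0`` are hypermethylated in group_a.  With more than one
    sample per group candidates are MWU-tested and BH-filtered at
    ``params.alpha``; 1-vs-1 designs skip the test (q = NaN).
    """
    cols_a = matrix.columns(group_a)
    cols_b = matrix.columns(group_b)
    if cols_a.size < 1 or cols_b.size < 1:
        raise ValueError("each group needs at least one sample")
    tested = cols_a.size > 1 and cols_b.size > 1

    beta = matrix.levels(params.min_coverage)
    with np.errstate(invalid="ignore"):
        mean_a = np.nanmean(beta[:, cols_a], axis=1)
        mean_b = np.nanmean(beta[:, cols_b], axis=1)
    valid = np.isfinite(mean_a) & np.isfinite(mean_b)

    chroms = matrix.sites["chrom"].to_numpy()
    positions = matrix.sites["pos"].to_numpy()

    candidates = []  # (chrom, start, end, n, ma, mb, d_seg)
    for chrom in dict.fromkeys(chroms):
        cmask = (chroms == chrom) & valid
        if not np.any(cmask):
            continue
        pos = positions[cmask]
        ma = mean_a[cmask]
        mb = mean_b[cmask]
        d = ma - mb
        for i, j in presegment(pos, params.max_gap, params.min_cpgs):
            seg_d = d[i:j]
            cumsum = np.concatenate(([0.0], np.cumsum(seg_d)))
            leaves: list = []
            _segment(
                cumsum, 0, j - i, params.min_diff / 2.0, params.min_diff, leaves
            )
            for lo, hi in _merge_leaves(seg_d, leaves, params.min_diff):
                if hi - lo < params.min_cpgs:
                    continue
                sl = slice(i + lo, i + hi)
                candidates.append(
                    (
                        chrom,
                        int(pos[i + lo]),
                        int(pos[i + hi - 1]) + 1,
                        hi - lo,
                        float(np.mean(ma[sl])),
                        float(np.mean(mb[sl])),
                        seg_d[lo:hi],
                    )
                )

    if not candidates:
        return []

    pvals = np.ones(len(candidates))
    stats_u = np.full(len(candidates), np.nan)
    if tested:
        for idx, (_, _, _, _, _, _, seg) in enumerate(candidates):
            if np.allclose(seg, 0):
                continue
            res = stats.mannwhitneyu(seg, -seg, alternative="two-sided")
            pvals[idx] = res.pvalue
            stats_u[idx] = res.statistic
        _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    else:
        qvals = np.full(len(candidates), np.nan)

    out = []
    for idx, (chrom, start, end, n, ma, mb, seg) in enumerate(candidates):
        delta = float(np.mean(seg))
        direction = classify_direction(delta)
        if direction == "excluded" or abs(delta) < params.min_diff:
            continue
        if tested and not qvals[idx] <= params.alpha:
            continue
        out.append(
            DMR(
                chrom=chrom,
                start=start,
                end=end,
                n_cpgs=n,
                mean_a=ma,
                mean_b=mb,
                delta=delta,
                direction=direction,
                statistic=float(stats_u[idx]),
                q_value=float(qvals[idx]) if tested else math.nan,
            )
        )
    return sorted(out, key=DMR.sort_key)
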