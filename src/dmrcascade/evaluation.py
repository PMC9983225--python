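"""Scoring called regions against planted ground truth."""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["match_regions", "RecoveryScore", "score_recovery"]


def _reciprocal(a, b, min_frac: float) -> bool:
    if a.chrom != b.chrom:
        return False
    ov = min(a.end, b.end) - max(a.start, b.start)
    if ov <= 0:
        return False
    return ov >= min_frac * (a.end - a.start) and ov >= min_frac * (b.end - b.start)


@dataclass(frozen=True)
class RecoveryScore:
    n_truth: int
    n_called: int
    n_truth_matched: int
    n_called_matched: int

    @property
    def recall(self) -> float:
        return self.n_truth_matched / self.n_truth if self.n_truth else float("nan")

    @property
    def precision(self) -> float:
        return (
            self.n_called_matched / self.n_called if self.n_called else float("nan")
        )


def match_regions(called, truth, min_reciprocal: float = 0.5):
    """Pair called and truth regions at reciprocal-overlap >= min_frac.

    Matching is many-to-many for counting purposes: a truth region is
    recovered if any call matches it, and a call is correct if it
    matches any truth region.  Directions, when present on both sides,
    must agree.
    """
    called = list(called)
    truth = list(truth)
    t_hit = [False] * len(truth)
    c_hit = [False] * len(called)
    for i, c in enumerate(called):
        for j, t in enumerate(truth):
            if not _reciprocal(c, t, min_reciprocal):
                continue
            cd = getattr(c, "direction", None)
            td = getattr(t, "direction", None)
            if cd is not None and td is not None and cd != td:
                continue
            c_hit[i] = True
            t_hit[j] = True
    return t_hit, c_hit


def score_recovery(called, truth, min_reciprocal: float = 0.5) -> RecoveryScore:
    t_hit, c_hit = match_regions(called, truth, min_reciprocal)
    return RecoveryScore(
        n_truth=len(t_hit),
        n_called=len(c_hit),
        n_truth_matched=sum(t_hit),
        n_called_matched=sum(c_hit),
    )
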