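"""Core region types shared across the pipeline.

A :class:`DMR` is a half-open genomic interval carrying the signed group
mean methylation difference (``delta``, on the beta scale) and its
direction label.  The subtraction order is fixed by the comparison that
produced the region — e.g. t(8;21) minus non-t(8;21), or de novo minus
complete-remission — so ``delta > 0`` means "hypermethylated" in the
first-named group and ``delta < 0`` means "hypomethylated".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

__all__ = [
    "DMR",
    "DirectedRegionSet",
    "classify_direction",
    "HYPER",
    "HYPO",
]

HYPER = "hyper"
HYPO = "hypo"


def classify_direction(delta: float) -> str:
    """Classify a signed methylation difference.

    Positive differences are hypermethylated, negative ones
    hypomethylated; an exact zero satisfies neither definition and is
    ``"excluded"``.
    """
    if not math.isfinite(delta):
        raise ValueError(f"delta must be finite, got {delta!r}")
    if delta > 0:
        return HYPER
    if delta < 0:
        return HYPO
    return "excluded"


@dataclass(frozen=True)
class DMR:
    """A differentially methylated region (0-based, half-open)."""

    chrom: str
    start: int
    end: int
    n_cpgs: int = 0
    mean_a: float = float("nan")
    mean_b: float = float("nan")
    delta: float = float("nan")
    direction: str = HYPER
    statistic: float = float("nan")
    q_value: float = float("nan")

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.direction not in (HYPER, HYPO):
            raise ValueError(f"invalid direction {self.direction!r}")
        if math.isfinite(self.delta) and self.delta != 0:
            if classify_direction(self.delta) != self.direction:
                raise ValueError(
                    f"direction {self.direction!r} inconsistent with "
                    f"delta {self.delta}"
                )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "DMR") -> bool:
        """>=1 bp shared under half-open arithmetic."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def sort_key(self):
        return (self.chrom, self.start, self.end)


def _sorted_regions(regions) -> tuple:
    return tuple(sorted(regions, key=DMR.sort_key))


@dataclass(frozen=True)
class DirectedRegionSet:
    """A named, sorted collection of directed regions.

    ``provenance`` records which comparison(s) produced the set;
    ``conflicts`` holds regions that overlapped an opposite-direction
    partner during the operation that built the set (reported, never
    silently dropped unless the operation's contract says so).
    """

    name: str
    regions: tuple = ()
    provenance: str = ""
    conflicts: tuple = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "regions", _sorted_regions(self.regions))
        object.__setattr__(self, "conflicts", tuple(self.conflicts))

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    def by_direction(self, direction: str) -> "DirectedRegionSet":
        return replace(
            self,
            name=f"{self.name}.{direction}",
            regions=tuple(r for r in self.regions if r.direction == direction),
            conflicts=(),
        )

    @property
    def n_hyper(self) -> int:
        return sum(1 for r in self.regions if r.direction == HYPER)

    @property
    def n_hypo(self) -> int:
        return sum(1 for r in self.regions if r.direction == HYPO)
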