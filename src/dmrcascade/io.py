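"""Readers and writers for the pipeline's file dialects.

All in-memory coordinates are 0-based, half-open (BED convention);
coverage files are converted at the boundary.  Readers validate and
reject coordinate violations; writers emit files their readers accept
losslessly.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .regions import DMR, DirectedRegionSet

log = logging.getLogger(__name__)

__all__ = [
    "CpGSite",
    "GeneModel",
    "MethylationMatrix",
    "read_coverage_file",
    "write_coverage_file",
    "read_bed",
    "write_bed",
    "read_gene_models",
    "write_gene_models",
    "read_sample_sheet",
    "write_sample_sheet",
]


@dataclass(frozen=True)
class CpGSite:
    """One CpG's read counts in one sample (0-based position)."""

    chrom: str
    pos: int
    meth_reads: int
    total_reads: int

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"negative position {self.pos}")
        if not 0 <= self.meth_reads <= self.total_reads:
            raise ValueError(
                f"invalid counts meth={self.meth_reads} total={self.total_reads} "
                f"at {self.chrom}:{self.pos}"
            )


@dataclass(frozen=True)
class GeneModel:
    """A transcript model; TSS is the strand-dependent 5' end."""

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not 0 <= self.tx_start < self.tx_end:
            raise ValueError(
                f"invalid transcript interval {self.tx_start}-{self.tx_end}"
            )

    @property
    def tss(self) -> int:
        """0-based TSS coordinate: tx_start on +, tx_end-1 on -."""
        return self.tx_start if self.strand == "+" else self.tx_end - 1


class MethylationMatrix:
    """Per-CpG methylated/total counts for a cohort on a shared site index.

    Parameters
    ----------
    sites
        DataFrame with columns ``chrom``, ``pos`` (0-based), sorted and
        unique within chromosome.
    meth, total
        Integer arrays of shape ``(n_sites, n_samples)``.  A missing CpG
        in a sample is encoded as ``total == 0`` and excluded from that
        sample's level computation, never imputed.
    samples
        DataFrame with columns ``sample_id``, ``group``, ``pair_id``,
        ``timepoint``.
    """

    def __init__(
        self,
        sites: pd.DataFrame,
        meth: np.ndarray,
        total: np.ndarray,
        samples: pd.DataFrame,
    ) -> None:
        sites = sites.reset_index(drop=True)
        if list(sites.columns[:2]) != ["chrom", "pos"]:
            raise ValueError("sites must have columns chrom, pos")
        meth = np.asarray(meth)
        total = np.asarray(total)
        if meth.shape != total.shape or meth.shape[0] != len(sites):
            raise ValueError("count array shapes do not match the site index")
        if meth.shape[1] != len(samples):
            raise ValueError("count array width does not match sample sheet")
        if np.any(meth > total) or np.any(meth < 0):
            raise ValueError("methylated counts must satisfy 0 <= meth <= total")
        key = sites[["chrom", "pos"]]
        if key.duplicated().any():
            raise ValueError("duplicate (chrom, pos) in site index")
        order = np.lexsort((sites["pos"].to_numpy(), sites["chrom"].to_numpy()))
        if not np.array_equal(order, np.arange(len(sites))):
            sites = sites.iloc[order].reset_index(drop=True)
            meth = meth[order]
            total = total[order]
        self.sites = sites
        self.meth = meth
        self.total = total
        self.samples = samples.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples["sample_id"])

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def columns(self, sample_ids) -> np.ndarray:
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in idx]
        if missing:
            raise KeyError(f"unknown sample(s): {missing}")
        return np.array([idx[s] for s in sample_ids], dtype=int)

    def levels(self, min_coverage: int = 1) -> np.ndarray:
        """Per-site, per-sample beta = meth/total; NaN below min_coverage."""
        with np.errstate(divide="ignore", invalid="ignore"):
            beta = self.meth / self.total
        beta = np.where(self.total >= max(1, min_coverage), beta, np.nan)
        return beta

    @classmethod
    def from_coverage_files(
        cls, paths: dict, samples: pd.DataFrame
    ) -> "MethylationMatrix":
        """Assemble a cohort matrix from per-sample coverage files.

        ``paths`` maps sample_id -> file path.  The union of sites is
        used; a site absent from a sample gets total 0 there.
        """
        frames = {}
        for sid in samples["sample_id"]:
            frames[sid] = read_coverage_file(paths[sid])
        keys = pd.concat(
            [f[["chrom", "pos"]] for f in frames.values()], ignore_index=True
        ).drop_duplicates()
        keys = keys.sort_values(["chrom", "pos"]).reset_index(drop=True)
        index = pd.MultiIndex.from_frame(keys)
        n, m = len(keys), len(frames)
        meth = np.zeros((n, m), dtype=np.int64)
        total = np.zeros((n, m), dtype=np.int64)
        for j, sid in enumerate(samples["sample_id"]):
            f = frames[sid].set_index(["chrom", "pos"])
            locs = index.get_indexer(f.index)
            meth[locs, j] = f["meth"].to_numpy()
            total[locs, j] = f["total"].to_numpy()
        return cls(keys, meth, total, samples)


def read_coverage_file(path) -> pd.DataFrame:
    """Read a Bismark-style coverage TSV into (chrom, pos, meth, total).

    Two single-CpG dialects are accepted and sniffed per file:

    * genuine Bismark coverage: 1-based ``start == end`` — position is
      ``start - 1``;
    * BED-like: 0-based ``end == start + 1`` — position is ``start``.

    The percentage column is recomputed from the counts; a mismatch
    above 0.5 points is logged as a warning.  ``meth > total`` (negative
    unmethylated count) is a hard error.  Unsorted input is sorted with
    a warning.
    """
    path = Path(path)
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}:{ln}: expected >=6 columns")
            chrom, start, end, pct, meth, unmeth = parts[:6]
            try:
                start, end = int(start), int(end)
                meth, unmeth = int(meth), int(unmeth)
                pct = float(pct)
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: non-numeric field") from exc
            if unmeth < 0 or meth < 0:
                raise ValueError(f"{path}:{ln}: negative read count")
            if end == start:
                pos = start - 1  # 1-based Bismark flavor
            elif end == start + 1:
                pos = start  # BED-like flavor
            else:
                raise ValueError(
                    f"{path}:{ln}: not a single-CpG record ({start},{end})"
                )
            if pos < 0:
                raise ValueError(f"{path}:{ln}: negative position")
            total = meth + unmeth
            if total > 0 and abs(100.0 * meth / total - pct) > 0.5:
                log.warning(
                    "%s:%d: percentage column %.2f disagrees with counts "
                    "%d/%d; recomputed",
                    path,
                    ln,
                    pct,
                    meth,
                    total,
                )
            rows.append((chrom, pos, meth, total))
    if not rows:
        log.warning("%s: empty coverage file", path)
        return pd.DataFrame(columns=["chrom", "pos", "meth", "total"])
    df = pd.DataFrame(rows, columns=["chrom", "pos", "meth", "total"])
    if not df[["chrom", "pos"]].equals(
        df[["chrom", "pos"]].sort_values(["chrom", "pos"]).reset_index(drop=True)
    ):
        log.warning("%s: unsorted coverage file; sorting", path)
        df = df.sort_values(["chrom", "pos"]).reset_index(drop=True)
    return df


def write_coverage_file(df: pd.DataFrame, path) -> None:
    """Write (chrom, pos, meth, total) as BED-like coverage TSV."""
    with open(path, "w") as fh:
        for chrom, pos, meth, total in df[
            ["chrom", "pos", "meth", "total"]
        ].itertuples(index=False):
            pct = 100.0 * meth / total if total else 0.0
            fh.write(
                f"{chrom}\t{pos}\t{pos + 1}\t{pct:.6g}\t{meth}\t{total - meth}\n"
            )


# BED6 + delta, direction, n_cpgs, mean_a, mean_b, statistic, q_value
_BED_EXTRA = ("delta", "direction", "n_cpgs", "mean_a", "mean_b", "statistic", "q_value")


def write_bed(regions, path, name: str = "") -> None:
    """Write DMRs as BED6+7; lossless round-trip with :func:`read_bed`."""
    regions = sorted(regions, key=DMR.sort_key)
    with open(path, "w") as fh:
        for i, r in enumerate(regions):
            label = f"{name or 'DMR'}_{i + 1:05d}"
            fh.write(
                "\t".join(
                    [
                        r.chrom,
                        str(r.start),
                        str(r.end),
                        label,
                        "0",
                        ".",
                        repr(float(r.delta)),
                        r.direction,
                        str(r.n_cpgs),
                        repr(float(r.mean_a)),
                        repr(float(r.mean_b)),
                        repr(float(r.statistic)),
                        repr(float(r.q_value)),
                    ]
                )
                + "\n"
            )


def read_bed(path) -> list[DMR]:
    """Read BED3+ into DMRs; extra columns restore delta/direction etc."""
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: expected >=3 columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: non-numeric coordinates") from exc
            if start >= end or start < 0:
                raise ValueError(f"{path}:{ln}: invalid interval {start}-{end}")
            kwargs = {}
            if len(parts) >= 13:
                kwargs = dict(
                    delta=float(parts[6]),
                    direction=parts[7],
                    n_cpgs=int(parts[8]),
                    mean_a=float(parts[9]),
                    mean_b=float(parts[10]),
                    statistic=float(parts[11]),
                    q_value=float(parts[12]),
                )
            elif len(parts) >= 8:
                kwargs = dict(delta=float(parts[6]), direction=parts[7])
            out.append(DMR(chrom=chrom, start=start, end=end, **kwargs))
    return sorted(out, key=DMR.sort_key)


def write_region_set(rs: DirectedRegionSet, path) -> None:
    write_bed(rs.regions, path, name=rs.name)


def read_gene_models(path) -> list[GeneModel]:
    """Read a gene-model TSV (gene_id, chrom, strand, tx_start, tx_end).

    A BED6 layout (chrom, start, end, gene_id, score, strand) is also
    accepted.  Strand is mandatory — the promoter rule depends on it.
    Duplicate gene ids are an error; output is sorted by coordinate.
    """
    genes = []
    seen = set()
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise ValueError(f"{path}:{ln}: expected >=5 columns")
            if parts[2] in ("+", "-"):  # gene_id chrom strand start end
                gid, chrom, strand = parts[0], parts[1], parts[2]
                start, end = int(parts[3]), int(parts[4])
            elif len(parts) >= 6 and parts[5] in ("+", "-"):  # BED6
                chrom, gid, strand = parts[0], parts[3], parts[5]
                start, end = int(parts[1]), int(parts[2])
            else:
                raise ValueError(f"{path}:{ln}: missing strand")
            if gid in seen:
                raise ValueError(f"{path}:{ln}: duplicate gene_id {gid!r}")
            seen.add(gid)
            genes.append(GeneModel(gid, chrom, strand, start, end))
    return sorted(genes, key=lambda g: (g.chrom, g.tx_start, g.tx_end))


def write_gene_models(genes, path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda g: (g.chrom, g.tx_start, g.tx_end)):
            fh.write(
                f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.tx_start}\t{g.tx_end}\n"
            )


_SHEET_COLS = ["sample_id", "group", "pair_id", "timepoint"]


def read_sample_sheet(path) -> pd.DataFrame:
    """Read the sample sheet CSV (sample_id, group, pair_id, timepoint)."""
    df = pd.read_csv(path, dtype=str).fillna("")
    missing = [c for c in _SHEET_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"sample sheet missing column(s) {missing}")
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in sample sheet")
    return df[_SHEET_COLS]


def write_sample_sheet(samples: pd.DataFrame, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_SHEET_COLS)
        for row in samples[_SHEET_COLS].itertuples(index=False):
            writer.writerow(row)
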