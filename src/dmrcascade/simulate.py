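"""Synthetic bisulfite cohorts with planted, direction-controlled DMRs.

The generator emulates the structure of a MethylC-capture AML cohort:
a small t(8;21) de novo group versus a larger non-t(8;21) group, de
novo/complete-remission pairs in both karyotype groups, and an
AML1-ETO-positive/-silenced cell line pair.  Per-CpG methylated counts
are drawn beta-binomially (real bisulfite data is overdispersed)
around a latent per-CpG level; planted regions shift that level by a
signed effect on the beta scale for the samples their contrast
elevates, and CR samples revert treatment-contrast effects, so every
downstream stage of the cascade has ground truth.

CpGs are laid down with exponential gaps, densified inside gene
promoter windows and planted regions (CpG-island behavior), which also
guarantees each callable planted region contains enough CpGs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .annotate import promoter_window
from .io import (
    GeneModel,
    MethylationMatrix,
    write_bed,
    write_coverage_file,
    write_gene_models,
    write_sample_sheet,
)
from .regions import DMR, classify_direction

__all__ = [
    "SimConfig",
    "PlantedDMR",
    "GenerationError",
    "simulate_gene_models",
    "simulate_methylation_cohort",
    "simulate_expression",
    "expression_groups",
    "write_cohort",
    "demo_config",
    "recovery_config",
    "null_config",
]

CONTRAST_TOKENS = ("group", "t821_treatment", "non_t821_treatment")


class GenerationError(RuntimeError):
    """A configuration that cannot produce a valid fixture."""


@dataclass(frozen=True)
class PlantedDMR:
    """A ground-truth region with a signed beta-scale effect.

    ``contrast`` names the comparison(s) the effect enters: "group"
    elevates the t(8;21) lineage (patients and the AE-positive cell
    line), "t821_treatment" / "non_t821_treatment" elevate the de novo
    samples of that karyotype and are reverted in their CR partners
    (reversal wins over group membership, so the de novo-minus-CR delta
    equals the planted effect).  ``n_cpgs`` is the minimum number of
    simulated CpGs the region must contain.
    """

    chrom: str
    start: int
    end: int
    effect_size: float
    contrast: tuple = ("group",)
    n_cpgs: int = 10
    linked_gene: str | None = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"invalid interval {self.start}-{self.end}")
        if not 0 < abs(self.effect_size) <= 0.9:
            raise ValueError("effect_size must be nonzero, |effect| <= 0.9")
        bad = [t for t in self.contrast if t not in CONTRAST_TOKENS]
        if bad or not self.contrast:
            raise ValueError(f"invalid contrast tokens {bad}")
        if self.n_cpgs < 1:
            raise ValueError("n_cpgs must be >= 1")

    @property
    def direction(self) -> str:
        return classify_direction(self.effect_size)

    @property
    def is_callable(self) -> bool:
        """Strong enough to be called at default thresholds."""
        return abs(self.effect_size) >= 0.2 and self.n_cpgs >= 5


@dataclass(frozen=True)
class SimConfig:
    """Study-shaped simulation parameters.

    Defaults emulate the cohort the cascade targets: 3 t(8;21) vs 25
    non-t(8;21) de novo patients, 2 t(8;21) and 3 non-t(8;21) de
    novo/CR pairs, one cell line pair, ~30x coverage, and a 2-chromosome
    / 200-gene / 20k-background-CpG demo genome.
    """

    n_chromosomes: int = 2
    chrom_length: int = 2_000_000
    n_genes: int = 200
    n_cpgs: int = 20_000
    cpg_spacing: float = 150.0
    island_density: float = 5.0
    coverage_mean: float = 30.0
    n_group_a: int = 3  # t(8;21) de novo
    n_group_b: int = 25  # non-t(8;21) de novo
    n_pairs_a: int = 2
    n_pairs_b: int = 3
    include_cell_lines: bool = True
    planted_dmrs: tuple = ()
    baseline_beta: tuple = (0.5, 0.5)
    dispersion: float = 0.02
    expr_n_a: int = 7  # t(8;21) transcriptome samples
    expr_n_b: int = 121  # non-t(8;21) transcriptome samples
    expr_log2_mean: float = 6.0
    expr_gene_sd: float = 2.0
    expr_sigma: float = 0.5
    linked_log2fc: float = -2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1 or self.chrom_length < 1:
            raise ValueError("need >= 1 chromosome of positive length")
        if self.n_genes < 0 or self.n_cpgs < 1:
            raise ValueError("n_genes must be >= 0, n_cpgs >= 1")
        if self.coverage_mean < 1:
            raise ValueError("coverage_mean must be >= 1")
        if not 0 < self.dispersion < 1:
            raise ValueError("dispersion must be in (0, 1)")
        if self.n_pairs_a > self.n_group_a or self.n_pairs_b > self.n_group_b:
            raise ValueError("pairs cannot exceed their de novo group size")
        if self.n_group_a < 1 or self.n_group_b < 1:
            raise ValueError("need >= 1 sample per de novo group")

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), stream])


# ---------------------------------------------------------------------------
# gene models


def simulate_gene_models(config: SimConfig) -> list[GeneModel]:
    """Non-overlapping transcripts on both strands, deterministic by seed."""
    rng = _rng(config, 1)
    genes: list[GeneModel] = []
    chroms = config.chrom_names()
    per_chrom = [
        config.n_genes // config.n_chromosomes
        + (1 if i < config.n_genes % config.n_chromosomes else 0)
        for i in range(config.n_chromosomes)
    ]
    gid = 0
    min_gap = 3000  # keeps promoter windows of neighbors from piling up
    margin = 5000
    for chrom, n in zip(chroms, per_chrom):
        if n == 0:
            continue
        lengths = rng.integers(3000, 12001, size=n)
        free = config.chrom_length - 2 * margin - int(lengths.sum())
        if free < (n + 1) * min_gap:
            raise GenerationError(
                f"{n} genes do not fit chromosome length {config.chrom_length}"
            )
        w = rng.random(n + 1)
        gaps = min_gap + (free - (n + 1) * min_gap) * w / w.sum()
        pos = margin
        for k in range(n):
            pos += gaps[k]
            start = int(pos)
            end = start + int(lengths[k])
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneModel(f"G{gid:04d}", chrom, strand, start, end))
            gid += 1
            pos = end
    return genes


# ---------------------------------------------------------------------------
# methylation cohort


def build_sample_sheet(config: SimConfig) -> pd.DataFrame:
    rows = []
    for k in range(config.n_group_a):
        pid = f"pA{k + 1}" if k < config.n_pairs_a else ""
        rows.append((f"t821_dn_{k + 1}", "t821", pid, "de_novo"))
    for k in range(config.n_pairs_a):
        rows.append((f"t821_cr_{k + 1}", "t821", f"pA{k + 1}", "cr"))
    for k in range(config.n_group_b):
        pid = f"pB{k + 1}" if k < config.n_pairs_b else ""
        rows.append((f"non_t821_dn_{k + 1}", "non_t821", pid, "de_novo"))
    for k in range(config.n_pairs_b):
        rows.append((f"non_t821_cr_{k + 1}", "non_t821", f"pB{k + 1}", "cr"))
    if config.include_cell_lines:
        rows.append(("cell_ae_pos", "cellline", "", "ae_pos"))
        rows.append(("cell_ae_neg", "cellline", "", "ae_neg"))
    return pd.DataFrame(
        rows, columns=["sample_id", "group", "pair_id", "timepoint"]
    )


def _sample_class(row) -> str:
    if row.group == "cellline":
        return row.timepoint  # ae_pos / ae_neg
    return f"{row.group}_{row.timepoint}"  # e.g. t821_de_novo


def _contribution(region: PlantedDMR, sample_class: str) -> float:
    c = region.contrast
    elevated = False
    if "group" in c and sample_class in ("t821_de_novo", "t821_cr", "ae_pos"):
        elevated = True
    if "t821_treatment" in c and sample_class == "t821_de_novo":
        elevated = True
    if "non_t821_treatment" in c and sample_class == "non_t821_de_novo":
        elevated = True
    # treatment removed the mark in remission, whatever the karyotype effect
    if "t821_treatment" in c and sample_class == "t821_cr":
        elevated = False
    if "non_t821_treatment" in c and sample_class == "non_t821_cr":
        elevated = False
    return region.effect_size if elevated else 0.0


_ALL_CLASSES = (
    "t821_de_novo",
    "t821_cr",
    "non_t821_de_novo",
    "non_t821_cr",
    "ae_pos",
    "ae_neg",
)


def _cpg_positions(config: SimConfig, genes, rng) -> pd.DataFrame:
    """Background CpGs plus dense islands in promoters and planted regions."""
    chroms = config.chrom_names()
    per_chrom = config.n_cpgs // config.n_chromosomes
    frames = []
    islands: dict[str, list] = {c: [] for c in chroms}
    for g in genes:
        p = promoter_window(g)
        islands[g.chrom].append((p.start, min(p.end, config.chrom_length)))
    for r in config.planted_dmrs:
        if r.chrom not in islands:
            raise GenerationError(f"planted region on unknown {r.chrom}")
        islands[r.chrom].append((r.start, min(r.end, config.chrom_length)))
    for chrom in chroms:
        gaps = 2 + np.floor(rng.exponential(config.cpg_spacing, per_chrom))
        pos = np.cumsum(gaps).astype(np.int64) + 1000
        pos = pos[pos < config.chrom_length]
        dense = []
        ivals = sorted(islands[chrom])
        merged = []
        for s, e in ivals:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        spacing = max(2.0, config.cpg_spacing / config.island_density)
        for s, e in merged:
            g = 2 + np.floor(
                rng.exponential(spacing, int((e - s) / spacing * 2) + 8)
            )
            p = s + np.cumsum(g).astype(np.int64)
            dense.append(p[p < e])
        allpos = np.unique(
            np.concatenate([pos] + dense) if dense else pos
        )
        frames.append(pd.DataFrame({"chrom": chrom, "pos": allpos}))
    return pd.concat(frames, ignore_index=True)


def simulate_methylation_cohort(
    config: SimConfig, genes: list[GeneModel]
) -> tuple[MethylationMatrix, pd.DataFrame]:
    """Draw the cohort count matrix and return it with the truth table.

    Raises :class:`GenerationError` if a planted region ends up with
    fewer CpGs than its ``n_cpgs``, or if a linked gene is absent or
    its promoter window does not overlap the region.
    """
    gene_ids = {g.gene_id: g for g in genes}
    for r in config.planted_dmrs:
        if r.linked_gene is not None:
            g = gene_ids.get(r.linked_gene)
            if g is None:
                raise GenerationError(f"linked gene {r.linked_gene!r} not simulated")
            p = promoter_window(g)
            if not (r.start < p.end and p.start < r.end):
                raise GenerationError(
                    f"planted region {r.chrom}:{r.start}-{r.end} does not "
                    f"overlap the promoter of {r.linked_gene}"
                )

    rng = _rng(config, 2)
    sites = _cpg_positions(config, genes, rng)
    samples = build_sample_sheet(config)
    classes = [_sample_class(row) for row in samples.itertuples(index=False)]
    n_sites, n_samples = len(sites), len(samples)

    chrom_arr = sites["chrom"].to_numpy()
    pos_arr = sites["pos"].to_numpy()

    # per-region CpG masks + truth table
    shift = np.zeros((n_sites, len(_ALL_CLASSES)))
    class_idx = {c: i for i, c in enumerate(_ALL_CLASSES)}
    truth_rows = []
    planted_mask = np.zeros(n_sites, dtype=bool)
    for r in config.planted_dmrs:
        m = (chrom_arr == r.chrom) & (pos_arr >= r.start) & (pos_arr < r.end)
        n_in = int(m.sum())
        if n_in < r.n_cpgs:
            raise GenerationError(
                f"planted region {r.chrom}:{r.start}-{r.end} contains "
                f"{n_in} CpGs < required {r.n_cpgs}"
            )
        planted_mask |= m
        for c in _ALL_CLASSES:
            shift[m, class_idx[c]] += _contribution(r, c)
        truth_rows.append(
            (
                r.chrom,
                r.start,
                r.end,
                r.effect_size,
                r.direction,
                "+".join(r.contrast),
                n_in,
                r.linked_gene or "",
            )
        )
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "chrom",
            "start",
            "end",
            "effect_size",
            "direction",
            "contrast",
            "n_cpgs",
            "linked_gene",
        ],
    ).sort_values(["chrom", "start", "end"]).reset_index(drop=True)

    a, b = config.baseline_beta
    base = rng.beta(a, b, n_sites)
    # inside planted regions: draw a baseline with headroom so every
    # sample class's shifted level stays in [0.05, 0.95]
    if planted_mask.any():
        min_s = shift[planted_mask].min(axis=1)
        max_s = shift[planted_mask].max(axis=1)
        lo = np.maximum(0.05, 0.05 - min_s)
        hi = np.minimum(0.95, 0.95 - max_s)
        if np.any(lo >= hi):
            raise GenerationError("planted effects leave no baseline headroom")
        base[planted_mask] = lo + rng.random(int(planted_mask.sum())) * (hi - lo)

    col_class = np.array([class_idx[c] for c in classes])
    mu = np.clip(base[:, None] + shift[:, col_class], 0.01, 0.99)

    total = rng.poisson(config.coverage_mean, size=(n_sites, n_samples))
    s = (1.0 - config.dispersion) / config.dispersion
    p = rng.beta(mu * s, (1.0 - mu) * s)
    meth = rng.binomial(total, p)

    matrix = MethylationMatrix(sites, meth, total, samples)
    return matrix, truth


# ---------------------------------------------------------------------------
# expression


def expression_groups(config: SimConfig) -> tuple[list[str], list[str]]:
    """Column names of the two expression-cohort groups."""
    a = [f"expr_t821_{k + 1}" for k in range(config.expr_n_a)]
    b = [f"expr_non_t821_{k + 1}" for k in range(config.expr_n_b)]
    return a, b


def simulate_expression(
    config: SimConfig, genes: list[GeneModel], truth: pd.DataFrame
) -> pd.DataFrame:
    """Log2 expression for a transcriptome cohort; linked genes silenced.

    The expression cohort is independent of the methylation cohort
    (mirroring a public transcriptome resource queried alongside a
    small sequencing study): ``expr_n_a`` t(8;21) and ``expr_n_b``
    non-t(8;21) samples.  Gene baselines are log-normal (normal on the
    log2 scale); genes linked to a planted promoter region receive
    ``linked_log2fc`` in the t(8;21) group.  Deterministic under the
    config seed.
    """
    rng = _rng(config, 3)
    cols_a, cols_b = expression_groups(config)
    sample_ids = cols_a + cols_b
    n_g = len(genes)
    base = rng.normal(config.expr_log2_mean, config.expr_gene_sd, n_g)
    expr = base[:, None] + rng.normal(0.0, config.expr_sigma, (n_g, len(sample_ids)))
    linked = set(truth.loc[truth["linked_gene"] != "", "linked_gene"])
    gene_index = [g.gene_id for g in genes]
    for i, gid in enumerate(gene_index):
        if gid in linked:
            expr[i, : len(cols_a)] += config.linked_log2fc
    return pd.DataFrame(expr, index=pd.Index(gene_index, name="gene_id"),
                        columns=sample_ids)


# ---------------------------------------------------------------------------
# fixture writing


def write_cohort(config: SimConfig, out_dir) -> dict:
    """Write the full fixture set (coverage TSVs, truth BED, genes,
    expression, sample sheet) and return the in-memory objects."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genes = simulate_gene_models(config)
    matrix, truth = simulate_methylation_cohort(config, genes)
    expr = simulate_expression(config, genes, truth)

    cov_dir = out / "coverage"
    cov_dir.mkdir(exist_ok=True)
    for j, sid in enumerate(matrix.sample_ids):
        df = pd.DataFrame(
            {
                "chrom": matrix.sites["chrom"],
                "pos": matrix.sites["pos"],
                "meth": matrix.meth[:, j],
                "total": matrix.total[:, j],
            }
        )
        df = df[df["total"] > 0]
        write_coverage_file(df, cov_dir / f"{sid}.cov.tsv")

    truth_regions = [
        DMR(
            chrom=t.chrom,
            start=t.start,
            end=t.end,
            n_cpgs=t.n_cpgs,
            delta=t.effect_size,
            direction=t.direction,
        )
        for t in truth.itertuples(index=False)
    ]
    write_bed(truth_regions, out / "truth.bed", name="truth")
    write_gene_models(genes, out / "genes.tsv")
    expr.to_csv(out / "expression.tsv", sep="\t")
    write_sample_sheet(matrix.samples, out / "samples.csv")
    cols_a, cols_b = expression_groups(config)
    expr_sheet = pd.DataFrame(
        {
            "sample_id": cols_a + cols_b,
            "group": ["t821"] * len(cols_a) + ["non_t821"] * len(cols_b),
            "pair_id": "",
            "timepoint": "",
        }
    )
    write_sample_sheet(expr_sheet, out / "expression_samples.csv")
    return {"genes": genes, "matrix": matrix, "truth": truth, "expression": expr}


# ---------------------------------------------------------------------------
# canned configurations


def _intergenic_slots(config: SimConfig, genes, width=3000, min_gap=9000):
    """Centers of large intergenic gaps, clear of promoter reach."""
    slots = []
    reach = 2300  # beyond promoter upstream span, plus margin
    by_chrom: dict[str, list] = {c: [] for c in config.chrom_names()}
    for g in genes:
        p = promoter_window(g)
        by_chrom[g.chrom].append((min(p.start, g.tx_start), max(p.end, g.tx_end)))
    for chrom, ivals in by_chrom.items():
        ivals.sort()
        bounds = [(0, ivals[0][0])] if ivals else [(0, config.chrom_length)]
        for (s1, e1), (s2, e2) in zip(ivals[:-1], ivals[1:]):
            bounds.append((e1, s2))
        if ivals:
            bounds.append((ivals[-1][1], config.chrom_length))
        for s, e in bounds:
            lo, hi = s + reach, e - reach
            stride = width + min_gap
            k = (hi - lo) // stride
            for i in range(int(k)):
                a = lo + i * stride + min_gap // 2
                slots.append((chrom, int(a), int(a) + width))
    return slots


def demo_config(seed: int = 0) -> SimConfig:
    """The default demo cohort: planted regions covering every contrast.

    Plants decitabine-responsive t(8;21) regions (group + t(8;21)
    treatment, the DMR7-destined truth; hyper ones at gene promoters
    with silenced expression), plus distractors that must be filtered
    out: group-only, t(8;21)-treatment-only, non-t(8;21)-treatment-only
    and shared-treatment regions.
    """
    cfg = SimConfig(seed=seed)
    genes = simulate_gene_models(cfg)
    slots = _intergenic_slots(cfg, genes, min_gap=2000)
    if len(slots) < 26:
        raise GenerationError("demo genome has too few intergenic slots")
    planted: list[PlantedDMR] = []

    # DMR7-destined hyper regions at promoters, linked to expression
    step = max(1, len(genes) // 8)
    linked_genes = [genes[i] for i in range(0, step * 8, step)]
    for g in linked_genes:
        p = promoter_window(g)
        planted.append(
            PlantedDMR(
                chrom=g.chrom,
                start=p.start,
                end=p.end,
                effect_size=+0.4,
                contrast=("group", "t821_treatment"),
                n_cpgs=10,
                linked_gene=g.gene_id,
            )
        )

    def take(n, effect, contrast):
        for _ in range(n):
            chrom, s, e = slots.pop(0)
            planted.append(
                PlantedDMR(
                    chrom=chrom,
                    start=s,
                    end=e,
                    effect_size=effect,
                    contrast=contrast,
                    n_cpgs=10,
                )
            )

    take(6, -0.4, ("group", "t821_treatment"))  # DMR7-destined hypo
    take(3, +0.4, ("group",))  # t(8;21) signature only -> stops at DMR3
    take(3, -0.4, ("group",))
    take(3, +0.4, ("t821_treatment",))  # response only -> stops at DMR6
    take(3, -0.4, ("t821_treatment",))
    take(2, +0.4, ("non_t821_treatment",))
    take(2, -0.4, ("non_t821_treatment",))
    # shared treatment response -> reaches DMR4 and DMR5, removed at DMR6
    take(2, +0.4, ("t821_treatment", "non_t821_treatment"))
    take(2, -0.4, ("t821_treatment", "non_t821_treatment"))

    return replace(cfg, planted_dmrs=tuple(planted))


def dmr7_truth(config: SimConfig) -> list[PlantedDMR]:
    """Planted regions expected to survive to DMR7."""
    return [
        r
        for r in config.planted_dmrs
        if "group" in r.contrast
        and "t821_treatment" in r.contrast
        and "non_t821_treatment" not in r.contrast
    ]


def recovery_config(seed: int = 0, n_regions: int = 60) -> SimConfig:
    """Two balanced 5-sample groups with >=50 strong planted DMRs.

    Effects alternate in sign and range over |0.3|..|0.5|; used to
    score plain two-group caller recovery.
    """
    cfg = SimConfig(
        seed=seed,
        n_genes=40,
        n_group_a=5,
        n_group_b=5,
        n_pairs_a=0,
        n_pairs_b=0,
        include_cell_lines=False,
    )
    genes = simulate_gene_models(cfg)
    slots = _intergenic_slots(cfg, genes, min_gap=6000)
    if len(slots) < n_regions:
        raise GenerationError("recovery genome has too few intergenic slots")
    planted = []
    for k in range(n_regions):
        chrom, s, e = slots[k]
        effect = (0.3 + 0.05 * (k % 5)) * (1 if k % 2 == 0 else -1)
        planted.append(
            PlantedDMR(chrom=chrom, start=s, end=e, effect_size=effect, n_cpgs=10)
        )
    return replace(cfg, planted_dmrs=tuple(planted))


def null_config(seed: int = 0) -> SimConfig:
    """Effect-free cohort on a reduced genome, for calibration loops."""
    return SimConfig(
        seed=seed,
        n_chromosomes=1,
        chrom_length=1_000_000,
        n_genes=40,
        n_cpgs=5_000,
    )
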