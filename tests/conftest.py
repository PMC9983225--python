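import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import dmrcascade as dc

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def demo_cohort():
    """The default demo cohort: genes, counts, truth, cascade, expression."""
    cfg = dc.demo_config(seed=1)
    genes = dc.simulate_gene_models(cfg)
    matrix, truth = dc.simulate_methylation_cohort(cfg, genes)
    cascade = dc.run_cascade(matrix)
    expr = dc.simulate_expression(cfg, genes, truth)
    return {
        "config": cfg,
        "genes": genes,
        "matrix": matrix,
        "truth": truth,
        "cascade": cascade,
        "expression": expr,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(20230303)


def random_region_set(rng, n, name="set", chroms=("chr1", "chr2"), span=20_000):
    """Random directed regions for oracle comparisons."""
    regions = []
    for _ in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, span))
        length = int(rng.integers(1, 400))
        delta = float(rng.uniform(0.2, 0.6)) * (1 if rng.random() < 0.5 else -1)
        regions.append(
            dc.DMR(
                chrom=chrom,
                start=start,
                end=start + length,
                delta=delta,
                direction="hyper" if delta > 0 else "hypo",
            )
        )
    return dc.DirectedRegionSet(name, regions)


def truth_regions(truth_df):
    """Planted-truth rows as DMR objects for matching."""
    return [
        dc.DMR(
            chrom=t.chrom,
            start=t.start,
            end=t.end,
            delta=t.effect_size,
            direction=t.direction,
        )
        for t in truth_df.itertuples(index=False)
    ]
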