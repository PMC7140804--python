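import numpy as np
import pandas as pd
import pytest

from dsprsleep import simpanel as sp
from dsprsleep.sleepmetrics import PhenotypeTable


@pytest.fixture(scope="session")
def small_genome():
    """One 5 Mb / 100 cM chromosome on a 100 kb grid (50 positions)."""
    return sp.GenomeMap([sp.Chromosome("2", 5_000_000, 100.0)], spacing_bp=100_000)


@pytest.fixture(scope="session")
def panel200(small_genome):
    mosaics = sp.simulate_panel(200, small_genome, seed=11)
    return sp.mosaics_to_probs(mosaics, small_genome)


@pytest.fixture(scope="session")
def planted_scan(small_genome, panel200):
    """A planted 10%-PVE QTL with its per-fly phenotypes and genotype means."""
    rng = np.random.default_rng(5)
    qtl = sp.PlantedQTL("2", 2_500_000, sp.random_effect_vector(rng), trait="LST", pve=0.10)
    per_fly = sp.simulate_phenotypes(
        panel200, [qtl], h2_target=0.5, subpop_shift=0.5,
        n_flies_per_genotype=8, seed=6,
    )
    table = PhenotypeTable.from_per_fly(per_fly, transform_spec=())
    return qtl, table


def make_toy_panel(probs, genotypes=None, subpop=None, n_founders=8, chrom="2"):
    """FounderProbPanel from an explicit (G, P, 2k) array on a unit grid."""
    probs = np.asarray(probs, dtype=float)
    g, p, _ = probs.shape
    grid = pd.DataFrame(
        {"chrom": chrom, "bp": np.arange(1, p + 1) * 1000, "cM": np.arange(p, dtype=float)}
    )
    return sp.FounderProbPanel(
        genotypes=genotypes or [f"G{i:03d}" for i in range(g)],
        subpop=np.asarray(subpop if subpop is not None else np.ones(g, dtype=int)),
        grid=grid,
        probs=probs,
        n_founders=n_founders,
    )
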