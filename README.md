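# dsprsleep

Sleep/activity phenotyping and founder-haplotype QTL mapping for
multiparental *Drosophila* panels.

Fly sleep is measured behaviourally: a fly in a Drosophila Activity Monitor
(DAM) tube breaks an infrared beam when it moves, and a run of **≥ 5
consecutive minutes with zero beam breaks** is scored as a sleep bout.  From
minute-resolution traces this package derives eight phenotypes per fly —
sleep time, bout number, mean bout length and waking activity, each in the
12 h light and dark phase (LST/DST, LBN/DBN, LBL/DBL, LWA/DWA) — and maps
the loci underlying their genetic variation in an F1 panel derived from two
8-founder synthetic populations (pA maternal × pB paternal recombinant
inbred lines, in two subpopulations).

`dsprsleep` is aimed at quantitative geneticists working with multiparental
panels who want a tested, scriptable re-implementation of this analysis, and
it ships a synthetic-data generator so that the entire pipeline can be
exercised, calibrated and unit-tested without access to panel data.

## The model

At every grid position each genotype carries 16 additive founder
probabilities (8 per parental panel, each 8-block summing to 1).  For each
trait, genotype mean phenotype is regressed on those probabilities with a
subpopulation covariate, and evidence is summarised as

```
LOD = (n/2) · log10(RSS_null / RSS_full)
```

where the null model holds intercept + covariates only.  Genomewide
significance comes from permutations of genotype means (within
subpopulation) — the threshold at level α is the empirical (1−α) quantile of
the per-permutation genomewide maximum LOD.  Support intervals are 3-LOD
drops from the peak; QTL effect size is the percentage of among-genotype
variance explained (PVE, df-adjusted); founder effects are phenotype means
over genotypes hard-assigned to a founder haplotype, reported when backed by
≥ 10 genotypes.  Trait-specific QTL with overlapping support intervals are
merged into QTL groups, prioritised by Pearson correlation of founder
effects against overlapping cis-eQTL, and tested for variant enrichment by
random placement of size-matched non-overlapping regions.  Broad-sense
heritability is estimated from per-fly replicates with genotype nested in
subpopulation:  H² = σ²_genotype / (σ²_genotype + σ²_residual).

## Worked example

Simulate a 400-genotype panel on a 100 cM chromosome, plant a QTL explaining
10% of among-genotype variance, and map it:

```python
import numpy as np
from dsprsleep import simpanel as sp, qtlscan as qs
from dsprsleep.sleepmetrics import PhenotypeTable

genome = sp.GenomeMap([sp.Chromosome("2", 5_000_000, 100.0)], spacing_bp=100_000)
mosaics = sp.simulate_panel(400, genome, generations=50, seed=1)
panel = sp.mosaics_to_probs(mosaics, genome)

rng = np.random.default_rng(2)
qtl = sp.PlantedQTL("2", 2_500_000, sp.random_effect_vector(rng), trait="LST", pve=0.10)
per_fly = sp.simulate_phenotypes(panel, [qtl], h2_target=0.5, subpop_shift=0.5,
                                 n_flies_per_genotype=8, seed=3)
table = PhenotypeTable.from_per_fly(per_fly, transform_spec=())

thr = qs.permutation_thresholds(table, panel, n_perm=200, alphas=(0.05,),
                                seed=4, trait="LST")[0.05]
scan = qs.scan_trait(table, panel, trait="LST")
peaks = qs.call_peaks(scan, thr, panel=panel, phenotypes=table, trait="LST")
print(f"5% genomewide threshold: LOD = {thr:.2f}")
for p in peaks:
    print(f"QTL at {p.chrom}:{p.peak_bp} ({p.peak_cm:.1f} cM), LOD {p.lod:.1f}, "
          f"3-LOD interval {p.lo_bp}-{p.hi_bp}, PVE {p.pve:.1f}%")
```

prints

```
5% genomewide threshold: LOD = 7.95
QTL at 2:2500001 (50.0 cM), LOD 15.6, 3-LOD interval 2400001-2600001, PVE 13.4%
```

The planted locus is recovered at its true position (50 cM), well above the
permutation threshold, with a 0.2 Mb support interval and an estimated PVE
close to the planted 10%.

The whole pipeline — panel simulation, DAM trace synthesis, phenotype
extraction, scans for all eight traits, QTL grouping, eQTL correlation,
enrichment and heritability — runs from one YAML config:

```
dsprsleep run --seed 17 --out runs/demo          # bundled scenario
dsprsleep run --config scenario.yaml --out runs/my
```

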