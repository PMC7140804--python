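"""Variant-in-interval enrichment by random non-overlapping region placement.

Given a set of point variants (e.g., prior GWAS hits) and a set of mapped
intervals, the observed count of variants inside the intervals is compared
with a resampling null: in each run, regions of the same sizes are placed
uniformly at random, non-overlapping and wholly within chromosomes, and the
variants falling inside them are counted.  Enrichment is called one-sided
against the 95th percentile of the null.  The naive binomial expectation
``n_variants * covered_fraction`` is also provided.

Coordinates are 1-based inclusive; BED input is converted on read.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


class EnrichmentError(ValueError):
    pass


def load_variants(path, fmt: str | None = None) -> pd.DataFrame:
    """Read variants as BED (0-based half-open; bp = start+1) or CSV with
    columns chrom, bp (1-based).  Format inferred from the suffix."""
    path = Path(path)
    fmt = fmt or ("bed" if path.suffix == ".bed" else "csv")
    if fmt == "bed":
        df = pd.read_csv(
            path, sep="\t", header=None, usecols=[0, 1], names=["chrom", "start"]
        )
        return pd.DataFrame({"chrom": df["chrom"], "bp": df["start"] + 1})
    df = pd.read_csv(path)
    return df[["chrom", "bp"]]


def collapse_duplicates(variants: pd.DataFrame) -> pd.DataFrame:
    """Collapse duplicate (chrom, bp) rows, keeping a count column."""
    return (
        variants.groupby(["chrom", "bp"], as_index=False)
        .size()
        .rename(columns={"size": "count"})
    )


def count_overlaps(
    variants: pd.DataFrame,
    intervals: pd.DataFrame,
    genome: Mapping[str, int] | None = None,
) -> int:
    """Number of variants with chrom match and lo <= bp <= hi over the
    interval set (closed intervals, 1-based).  When ``genome`` is given,
    variants on chromosomes outside it raise an error naming the offenders."""
    if genome is not None:
        _check_chroms(variants, genome)
    if len(intervals) == 0 or len(variants) == 0:
        return 0
    total = 0
    for chrom, sub in variants.groupby("chrom"):
        ivals = intervals[intervals["chrom"] == chrom]
        if ivals.empty:
            continue
        bp = sub["bp"].to_numpy()
        hit = np.zeros(len(bp), dtype=bool)
        for lo, hi in zip(ivals["lo_bp"], ivals["hi_bp"]):
            hit |= (bp >= lo) & (bp <= hi)
        total += int(hit.sum())
    return total


def expected_overlap(n_variants: int, covered_fraction: float) -> float:
    """Binomial expectation of variants inside intervals covering the given
    genome fraction, absent any functional overlap."""
    if not 0.0 <= covered_fraction <= 1.0:
        raise EnrichmentError("covered_fraction must be in [0, 1]")
    return n_variants * covered_fraction


@dataclass
class EnrichmentResult:
    observed: int
    expected: float
    null_mean: float
    null_q95: float
    null_sample: np.ndarray
    n_runs: int
    seed: int

    @property
    def enriched(self) -> bool:
        """One-sided call: observed beyond the null 95th percentile."""
        return self.observed > self.null_q95

    def to_dict(self) -> dict:
        return {
            "observed": self.observed,
            "expected": self.expected,
            "null_mean": self.null_mean,
            "null_q95": self.null_q95,
            "n_runs": self.n_runs,
            "seed": self.seed,
            "enriched": bool(self.enriched),
        }


def _check_chroms(variants: pd.DataFrame, genome: Mapping[str, int]) -> None:
    unknown = sorted(set(variants["chrom"]) - set(genome))
    if unknown:
        raise EnrichmentError(f"variants on unknown chromosomes: {unknown}")
    for chrom, sub in variants.groupby("chrom"):
        if (sub["bp"] < 1).any() or (sub["bp"] > genome[chrom]).any():
            raise EnrichmentError(f"variant outside chromosome {chrom}")


def _place_regions(
    sizes: Sequence[int],
    genome: Mapping[str, int],
    rng: np.random.Generator,
    max_attempts: int,
) -> pd.DataFrame:
    """One non-overlapping uniform placement of all regions (rejection
    sampling; deterministic given the generator state)."""
    chroms = list(genome)
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    rows = []
    for size in sorted(sizes, reverse=True):
        slots = np.array([max(genome[c] - size + 1, 0) for c in chroms], dtype=float)
        if slots.sum() == 0:
            raise EnrichmentError(f"region of {size} bp fits on no chromosome")
        pchrom = slots / slots.sum()
        for attempt in range(max_attempts):
            c = chroms[rng.choice(len(chroms), p=pchrom)]
            lo = int(rng.integers(1, genome[c] - size + 2))
            hi = lo + size - 1
            if all(hi < a or lo > b for a, b in placed[c]):
                placed[c].append((lo, hi))
                rows.append({"chrom": c, "lo_bp": lo, "hi_bp": hi})
                break
        else:
            raise EnrichmentError(
                f"could not place region of {size} bp after {max_attempts} attempts"
            )
    return pd.DataFrame(rows, columns=["chrom", "lo_bp", "hi_bp"])


def resampling_null(
    region_sizes: Sequence[int] | Mapping[str, int],
    genome: Mapping[str, int],
    variants: pd.DataFrame,
    n_runs: int = 1000,
    seed: int = 0,
    exclude: Sequence[str] | None = None,
    observed: int | None = None,
    max_attempts: int = 100_000,
) -> EnrichmentResult:
    """Null distribution of variant counts in randomly placed regions.

    ``region_sizes`` may be a mapping name -> size so that ``exclude`` can
    drop named regions before placement (the sensitivity analysis of
    removing one very large interval).  ``observed`` is the count in the
    true intervals, computed once by the caller via :func:`count_overlaps`;
    it is unaffected by the placement machinery.
    """
    if isinstance(region_sizes, Mapping):
        sizes = [
            int(s)
            for name, s in region_sizes.items()
            if not (exclude and name in exclude)
        ]
    else:
        if exclude:
            raise EnrichmentError("exclude requires named region sizes")
        sizes = [int(s) for s in region_sizes]
    if not sizes or min(sizes) < 1:
        raise EnrichmentError("region sizes must be positive and non-empty")
    if sum(sizes) > sum(genome.values()):
        raise EnrichmentError("regions exceed usable genome length")
    _check_chroms(variants, genome)

    rng = np.random.default_rng(seed)
    null = np.empty(n_runs, dtype=np.int64)
    for run in range(n_runs):
        regions = _place_regions(sizes, genome, rng, max_attempts)
        null[run] = count_overlaps(variants, regions)

    covered = sum(sizes) / sum(genome.values())
    return EnrichmentResult(
        observed=int(observed) if observed is not None else -1,
        expected=expected_overlap(len(variants), covered),
        null_mean=float(null.mean()),
        null_q95=float(np.quantile(null, 0.95)),
        null_sample=null,
        n_runs=n_runs,
        seed=seed,
    )
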