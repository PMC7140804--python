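"""Synthetic multiparental mapping panels with planted genetic signal.

This module generates data with the statistical structure assumed by the
rest of the pipeline, so every downstream stage can be exercised without the
real study data:

* two 8-founder panels (pA maternal, pB paternal) whose recombinant inbred
  lines (RILs) accumulated crossovers over ~50 generations of intercrossing
  followed by sibling-mated inbreeding;
* F1 genotypes formed by crossing a pA RIL to a pB RIL, in two
  subpopulations that may differ in founder composition (drift);
* planted QTL with multi-allelic 16-founder effect vectors;
* cis-eQTL expression tied to the local founder haplotype;
* per-fly, minute-resolution activity traces from a two-state (wake/sleep)
  Markov chain with phase-specific parameters.

Crossover model
---------------
Crossovers are Poisson on the genetic (cM) map with no interference.  RIL
formation is approximated by its expected map expansion rather than explicit
pedigree simulation: an advanced intercross maintained for ``g`` generations
expands the map by ``g/2`` (Darvasi & Soller), and sibling-mated RIL
derivation adds a factor of ~4 for autosomes (Haldane-Waddington), so each
RIL haplotype carries ``(g/2 + 4) * L_Morgan`` expected crossovers.  The RIL
constant is exposed as :data:`EFFECTIVE_RIL_MEIOSES`.

Founder-frequency drift is emulated by drawing block-wise founder
frequencies from a Dirichlet whose variance matches the Wright-Fisher
fixation index ``F = 1 - (1 - 1/(2*Ne))**g``, so drift away from the naive
1/8 grows with ``g`` and shrinks with ``Ne``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .damio import N_CHANNELS, ActivityMatrix

N_FOUNDERS = 8
PANELS = ("A", "B")
#: map-expansion contribution of sibling-mated RIL derivation (autosomes)
EFFECTIVE_RIL_MEIOSES = 4.0


class SimulationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# genome map
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Chromosome:
    name: str
    length_bp: int
    length_cm: float

    def __post_init__(self) -> None:
        if self.length_bp < 1 or self.length_cm < 0:
            raise SimulationError(f"bad chromosome {self.name}")


class GenomeMap:
    """Chromosome lengths plus a fixed-spacing scan grid.

    bp <-> cM conversion is linear per chromosome.  Grid positions are
    1-based bp at ``spacing_bp`` intervals, strictly increasing within each
    chromosome.
    """

    def __init__(self, chromosomes: Sequence[Chromosome], spacing_bp: int = 10_000):
        if not chromosomes:
            raise SimulationError("empty genome map")
        if spacing_bp < 1:
            raise SimulationError("spacing_bp must be >= 1")
        names = [c.name for c in chromosomes]
        if len(set(names)) != len(names):
            raise SimulationError("duplicate chromosome names")
        self.chromosomes = {c.name: c for c in chromosomes}
        self.spacing_bp = int(spacing_bp)
        frames = []
        for c in chromosomes:
            bp = np.arange(1, c.length_bp + 1, self.spacing_bp, dtype=np.int64)
            frames.append(
                pd.DataFrame(
                    {"chrom": c.name, "bp": bp, "cM": self.bp_to_cm(c.name, bp)}
                )
            )
        self.grid = pd.concat(frames, ignore_index=True)
        self._slices = {}
        start = 0
        for c in chromosomes:
            n = int((self.grid["chrom"] == c.name).sum())
            self._slices[c.name] = slice(start, start + n)
            start += n

    @property
    def n_positions(self) -> int:
        return len(self.grid)

    def chrom_slice(self, name: str) -> slice:
        return self._slices[name]

    def bp_to_cm(self, chrom: str, bp) -> np.ndarray:
        c = self.chromosomes[chrom]
        return np.asarray(bp, dtype=float) / c.length_bp * c.length_cm

    def cm_to_bp(self, chrom: str, cm) -> np.ndarray:
        c = self.chromosomes[chrom]
        if c.length_cm == 0:
            return np.full_like(np.asarray(cm, dtype=float), 1.0)
        return np.asarray(cm, dtype=float) / c.length_cm * c.length_bp

    def position_index(self, chrom: str, bp: int) -> int:
        """Index of the grid position nearest to (chrom, bp)."""
        if chrom not in self.chromosomes:
            raise SimulationError(f"unknown chromosome {chrom!r}")
        if not 1 <= bp <= self.chromosomes[chrom].length_bp:
            raise SimulationError(f"position {chrom}:{bp} outside chromosome")
        sl = self._slices[chrom]
        grid_bp = self.grid["bp"].to_numpy()[sl]
        return sl.start + int(np.argmin(np.abs(grid_bp - bp)))


def default_genome(spacing_bp: int = 200_000) -> GenomeMap:
    """A compact two-autosome synthetic genome used by bundled scenarios."""
    return GenomeMap(
        [Chromosome("2", 24_000_000, 108.0), Chromosome("3", 28_000_000, 110.0)],
        spacing_bp=spacing_bp,
    )


# ---------------------------------------------------------------------------
# mosaics
# ---------------------------------------------------------------------------

@dataclass
class FounderMosaic:
    """One F1 genotype: a pA-derived and a pB-derived haplotype mosaic.

    Each haplotype maps chromosome -> (break_bp, founders): ``break_bp`` are
    the last bp of each segment but the final one; ``founders`` (1-based,
    length ``len(break_bp)+1``) label the tiling segments.
    """

    genotype: str
    subpop: int
    maternal: dict[str, tuple[np.ndarray, np.ndarray]]
    paternal: dict[str, tuple[np.ndarray, np.ndarray]]

    def haplotype(self, panel: str) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        if panel == "A":
            return self.maternal
        if panel == "B":
            return self.paternal
        raise SimulationError(f"panel must be 'A' or 'B', got {panel!r}")

    def founder_at(self, panel: str, chrom: str, bp) -> np.ndarray:
        breaks, founders = self.haplotype(panel)[chrom]
        idx = np.searchsorted(breaks, np.asarray(bp), side="left")
        return founders[idx]

    def n_breakpoints(self, panel: str) -> int:
        return sum(len(b) for b, _ in self.haplotype(panel).values())


def drift_fixation_index(generations: int, ne: int) -> float:
    """Wright-Fisher probability of identity by descent after ``generations``."""
    return 1.0 - (1.0 - 1.0 / (2.0 * ne)) ** generations


def expected_breakpoints_per_haplotype(
    genome_map: GenomeMap,
    generations: int,
    n_founders: int = N_FOUNDERS,
    ne: int = 200,
) -> float:
    """Closed-form expectation of *visible* breakpoints per haplotype.

    Crossovers are Poisson with mean ``(g/2 + EFFECTIVE_RIL_MEIOSES) * L`` on
    ``L`` Morgans; a crossover is invisible when both flanking segments draw
    the same founder, which happens with probability ``E[sum p_i^2] =
    1/k + (1 - 1/k) * F`` under the drift model.
    """
    lam = (generations / 2.0 + EFFECTIVE_RIL_MEIOSES) * sum(
        c.length_cm / 100.0 for c in genome_map.chromosomes.values()
    )
    f = drift_fixation_index(generations, ne)
    coincide = 1.0 / n_founders + (1.0 - 1.0 / n_founders) * f
    return lam * (1.0 - coincide)


def _merge_equal(break_pos: np.ndarray, founders: np.ndarray):
    """Drop breakpoints between segments labelled with the same founder."""
    if len(break_pos) == 0:
        return break_pos, founders
    keep = founders[1:] != founders[:-1]
    return break_pos[keep], np.concatenate([[founders[0]], founders[1:][keep]])


def _dedupe_bp(break_bp: np.ndarray, founders: np.ndarray):
    """Remove zero-width segments created by rounding cM breaks to bp."""
    while len(break_bp) > 1:
        dup = np.flatnonzero(break_bp[1:] == break_bp[:-1])
        if dup.size == 0:
            break
        i = int(dup[0])  # segment i+1 is empty: drop break i and founder i+1
        break_bp = np.delete(break_bp, i)
        founders = np.delete(founders, i + 1)
    return _merge_equal(break_bp, founders)


def simulate_panel(
    n_genotypes: int,
    genome_map: GenomeMap,
    n_founders_per_panel: int = N_FOUNDERS,
    generations: int = 50,
    seed: int = 0,
    ne: int = 200,
    drift_block_cm: float = 25.0,
) -> list[FounderMosaic]:
    """Simulate F1 mosaics for ``n_genotypes`` RIL-by-RIL crosses.

    Genotypes alternate between subpopulation 1 (pA1 x pB2) and 2 (pA2 x
    pB1); founder frequencies are drawn independently per (panel, subpop,
    chromosome, ``drift_block_cm`` block), so composition differs between
    subpopulations and along the genome, as drift produces in a real panel.
    """
    if n_genotypes < 1:
        raise SimulationError("n_genotypes must be >= 1")
    if generations < 1:
        raise SimulationError("generations must be >= 1")
    if n_founders_per_panel < 2:
        raise SimulationError("need at least 2 founders per panel")
    rng = np.random.default_rng(seed)
    k = n_founders_per_panel
    f = drift_fixation_index(generations, ne)
    alpha0 = max(1.0 / f - 1.0, 1e-6)
    lam_per_morgan = generations / 2.0 + EFFECTIVE_RIL_MEIOSES

    # block founder frequencies: freqs[(panel, subpop, chrom)] -> (n_blocks, k)
    freqs: dict[tuple[str, int, str], np.ndarray] = {}
    n_blocks: dict[str, int] = {}
    for chrom, c in genome_map.chromosomes.items():
        n_blocks[chrom] = max(1, math.ceil(max(c.length_cm, 1e-9) / drift_block_cm))
        for panel in PANELS:
            for subpop in (1, 2):
                freqs[(panel, subpop, chrom)] = rng.dirichlet(
                    np.full(k, alpha0 / k), size=n_blocks[chrom]
                )

    mosaics = []
    half = math.ceil(n_genotypes / 2)
    for i in range(n_genotypes):
        subpop = 1 if i < half else 2
        haplos: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = {}
        for panel in PANELS:
            per_chrom = {}
            for chrom, c in genome_map.chromosomes.items():
                n_x = rng.poisson(lam_per_morgan * c.length_cm / 100.0)
                break_cm = np.sort(rng.uniform(0.0, c.length_cm, n_x))
                mids = np.concatenate(
                    [[0.0], break_cm, [c.length_cm]]
                )
                mids = (mids[:-1] + mids[1:]) / 2.0
                block = np.minimum(
                    (mids / drift_block_cm).astype(int), n_blocks[chrom] - 1
                )
                p = freqs[(panel, subpop, chrom)]
                u = rng.random(len(mids))
                founders = np.empty(len(mids), dtype=np.int64)
                for b in range(n_blocks[chrom]):
                    sel = block == b
                    if sel.any():
                        founders[sel] = (
                            np.searchsorted(np.cumsum(p[b]), u[sel]) + 1
                        ).clip(1, k)
                break_cm, founders = _merge_equal(break_cm, founders)
                break_bp = np.clip(
                    np.round(genome_map.cm_to_bp(chrom, break_cm)),
                    1,
                    max(c.length_bp - 1, 1),
                ).astype(np.int64)
                per_chrom[chrom] = _dedupe_bp(break_bp, founders)
            haplos[panel] = per_chrom
        mosaics.append(
            FounderMosaic(
                genotype=f"G{i + 1:04d}",
                subpop=subpop,
                maternal=haplos["A"],
                paternal=haplos["B"],
            )
        )
    return mosaics


def write_mosaic_bed(mosaics: Iterable[FounderMosaic], genome_map: GenomeMap, path) -> Path:
    """Export mosaic segments as BED (0-based, half-open)."""
    path = Path(path)
    lines = []
    for m in mosaics:
        for panel in PANELS:
            for chrom, (breaks, founders) in m.haplotype(panel).items():
                edges = np.concatenate(
                    [[0], breaks, [genome_map.chromosomes[chrom].length_bp]]
                )
                for s, e, f in zip(edges[:-1], edges[1:], founders):
                    lines.append(
                        f"{chrom}\t{int(s)}\t{int(e)}\t"
                        f"{m.genotype}|{panel}{int(f)}"
                    )
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# founder probabilities
# ---------------------------------------------------------------------------

@dataclass
class FounderProbPanel:
    """Per-genotype, per-grid-position 16 additive founder probabilities.

    ``probs`` has shape ``(n_genotypes, n_positions, 16)``: columns 0-7 are
    the maternal pA founders, 8-15 the paternal pB founders; each 8-block
    sums to 1 at every position.
    """

    genotypes: list[str]
    subpop: np.ndarray
    grid: pd.DataFrame
    probs: np.ndarray
    n_founders: int = N_FOUNDERS
    genome_map: GenomeMap | None = None

    def __post_init__(self) -> None:
        g, p, c = self.probs.shape
        if g != len(self.genotypes) or p != len(self.grid) or c != 2 * self.n_founders:
            raise SimulationError("probability array shape mismatch")

    @property
    def n_genotypes(self) -> int:
        return len(self.genotypes)

    @property
    def n_positions(self) -> int:
        return len(self.grid)

    def at(self, index: int) -> np.ndarray:
        """(n_genotypes, 16) probabilities at one grid position."""
        return self.probs[:, index, :]

    def position_index(self, chrom: str, bp: int) -> int:
        if self.genome_map is not None:
            return self.genome_map.position_index(chrom, bp)
        sel = self.grid["chrom"] == chrom
        if not sel.any():
            raise SimulationError(f"unknown chromosome {chrom!r}")
        sub = self.grid[sel]
        return int(sub.index[np.argmin(np.abs(sub["bp"].to_numpy() - bp))])

    def to_frame(self) -> pd.DataFrame:
        cols = [f"pA{i}" for i in range(1, self.n_founders + 1)] + [
            f"pB{i}" for i in range(1, self.n_founders + 1)
        ]
        g, p, _ = self.probs.shape
        df = pd.DataFrame(
            self.probs.reshape(g * p, -1), columns=cols
        )
        df.insert(0, "bp", np.tile(self.grid["bp"].to_numpy(), g))
        df.insert(0, "chrom", np.tile(self.grid["chrom"].to_numpy(), g))
        df.insert(0, "subpop", np.repeat(self.subpop, p))
        df.insert(0, "genotype", np.repeat(self.genotypes, p))
        return df

    def write_tsv(self, path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")
        return path

    @classmethod
    def read_tsv(cls, path) -> "FounderProbPanel":
        df = pd.read_csv(path, sep="\t")
        genotypes = list(dict.fromkeys(df["genotype"]))
        first = df[df["genotype"] == genotypes[0]]
        grid = first[["chrom", "bp"]].reset_index(drop=True).copy()
        grid["cM"] = np.nan
        cols = [c for c in df.columns if c.startswith(("pA", "pB"))]
        k = len(cols) // 2
        probs = (
            df[cols].to_numpy().reshape(len(genotypes), len(grid), 2 * k)
        )
        subpop = df.groupby("genotype", sort=False)["subpop"].first().to_numpy()
        return cls(genotypes, subpop, grid, probs, n_founders=k)


def mosaics_to_probs(
    mosaics: Sequence[FounderMosaic],
    genome_map: GenomeMap,
    certainty: float = 1.0,
) -> FounderProbPanel:
    """Founder probabilities from true mosaics.

    With ``certainty=1`` vectors are one-hot on the true founder; with
    ``certainty < 1`` the remaining mass is spread uniformly over the other
    founders (a crude stand-in for haplotype-inference uncertainty).
    """
    if not 0.0 < certainty <= 1.0:
        raise SimulationError("certainty must be in (0, 1]")
    k = N_FOUNDERS
    g, p = len(mosaics), genome_map.n_positions
    probs = np.zeros((g, p, 2 * k))
    off_diag = (1.0 - certainty) / (k - 1)
    for gi, m in enumerate(mosaics):
        for panel, offset in (("A", 0), ("B", k)):
            for chrom, c in genome_map.chromosomes.items():
                sl = genome_map.chrom_slice(chrom)
                bp = genome_map.grid["bp"].to_numpy()[sl]
                fo = m.founder_at(panel, chrom, bp)  # 1-based
                block = np.full((len(bp), k), off_diag)
                block[np.arange(len(bp)), fo - 1] = certainty
                probs[gi, sl, offset : offset + k] = block
    return FounderProbPanel(
        genotypes=[m.genotype for m in mosaics],
        subpop=np.array([m.subpop for m in mosaics]),
        grid=genome_map.grid.copy(),
        probs=probs,
        genome_map=genome_map,
    )


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

@dataclass
class PlantedQTL:
    """A planted QTL: position plus a 16-long founder effect vector.

    ``pve``, when given, is the fraction of among-genotype-*mean* variance
    the QTL should explain; the effect vector is then rescaled to hit it
    (its shape across founders — the allelic series — is preserved).
    """

    chrom: str
    bp: int
    effects: np.ndarray
    trait: str = "LST"
    pve: float | None = None

    def __post_init__(self) -> None:
        self.effects = np.asarray(self.effects, dtype=float)
        if self.effects.shape != (2 * N_FOUNDERS,):
            raise SimulationError("effect vector must have 16 entries")
        if not np.all(np.isfinite(self.effects)):
            raise SimulationError("effect vector must be finite")
        if np.unique(self.effects).size < 2:
            raise SimulationError("effect vector constant: no QTL")
        if self.pve is not None and not 0.0 < self.pve < 1.0:
            raise SimulationError("pve must be in (0, 1)")


def random_effect_vector(rng: np.random.Generator, scale: float = 1.0) -> np.ndarray:
    """A random multi-allelic founder effect vector (allelic series)."""
    return rng.normal(0.0, scale, 2 * N_FOUNDERS)


def simulate_phenotypes(
    probs: FounderProbPanel,
    planted_qtl: Sequence[PlantedQTL],
    h2_target: float,
    subpop_shift: float = 0.0,
    n_flies_per_genotype: int = 8,
    seed: int = 0,
    trait: str = "LST",
    baseline: float = 0.0,
) -> pd.DataFrame:
    """Per-fly phenotypes: QTL contributions + subpopulation shift + noise.

    Per-fly value = sum_q X_q . beta_q + shift*[subpop=2] + genotype noise +
    replicate noise.  Noise variances are solved so that broad-sense
    heritability equals ``h2_target`` in expectation:  with genotype-level
    variance sigma2_G, residual sigma2_E = sigma2_G*(1-h2)/h2.

    ``h2_target`` may be 0 (pure replicate noise; requires no planted QTL)
    or 1 (no replicate noise); values in between require genetic variance.
    When every planted QTL carries a ``pve``, sigma2_G is normalised to 1
    phenotype-unit^2, each QTL is scaled so that it explains ``pve`` of the
    variance of genotype means (sigma2_G + sigma2_E/n_flies), and extra
    genotype-level noise fills the remainder of sigma2_G.
    """
    if not 0.0 <= h2_target <= 1.0:
        raise SimulationError("h2_target must be in [0, 1]")
    if n_flies_per_genotype < 1:
        raise SimulationError("n_flies_per_genotype must be >= 1")
    rng = np.random.default_rng(seed)
    g = probs.n_genotypes

    contribs = []
    for q in planted_qtl:
        idx = probs.position_index(q.chrom, q.bp)
        v = probs.at(idx) @ q.effects
        contribs.append(v - v.mean())

    pves = [q.pve for q in planted_qtl]
    if any(p is not None for p in pves) and any(p is None for p in pves):
        raise SimulationError("either all or no planted QTL may carry a pve")

    if planted_qtl and pves[0] is not None:
        if h2_target == 0.0:
            raise SimulationError("h2_target=0 incompatible with planted QTL")
        sigma2_g = 1.0
        sigma2_e = sigma2_g * (1.0 - h2_target) / h2_target
        mean_var = sigma2_g + sigma2_e / n_flies_per_genotype
        total_qtl = 0.0
        for j, q in enumerate(planted_qtl):
            target = q.pve * mean_var
            raw = float(np.var(contribs[j]))
            if raw <= 0:
                raise SimulationError(f"QTL {j} has no realised variance")
            contribs[j] = contribs[j] * math.sqrt(target / raw)
            total_qtl += target
        g_noise_var = sigma2_g - total_qtl
        if g_noise_var < -1e-12:
            raise SimulationError("planted pve values exceed genotype variance")
        g_noise_var = max(g_noise_var, 0.0)
    else:
        genetic = np.sum(contribs, axis=0) if contribs else np.zeros(g)
        sigma2_g = float(np.var(genetic))
        g_noise_var = 0.0
        if not planted_qtl and h2_target > 0.0:
            sigma2_g, g_noise_var = 1.0, 1.0
        if h2_target == 0.0:
            if sigma2_g > 0:
                raise SimulationError("h2_target=0 incompatible with planted QTL")
            sigma2_e = 1.0
        elif h2_target == 1.0:
            sigma2_e = 0.0
        else:
            if sigma2_g <= 0:
                raise SimulationError("no genetic variance but h2_target > 0")
            sigma2_e = sigma2_g * (1.0 - h2_target) / h2_target

    genetic = np.sum(contribs, axis=0) if contribs else np.zeros(g)
    genetic = genetic + rng.normal(0.0, math.sqrt(g_noise_var), g)
    shift = np.where(probs.subpop == 2, subpop_shift, 0.0)
    geno_value = baseline + genetic + shift

    n = n_flies_per_genotype
    values = (
        np.repeat(geno_value, n)
        + rng.normal(0.0, math.sqrt(sigma2_e), g * n)
    )
    return pd.DataFrame(
        {
            "genotype": np.repeat(probs.genotypes, n),
            "subpop": np.repeat(probs.subpop, n),
            "fly": np.tile(np.arange(1, n + 1), g),
            "trait": trait,
            "value": values,
        }
    )


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

@dataclass
class CisGene:
    """A gene with a planted local (cis) eQTL."""

    gene: str
    chrom: str
    bp: int
    effects: np.ndarray

    def __post_init__(self) -> None:
        self.effects = np.asarray(self.effects, dtype=float)
        if self.effects.shape != (2 * N_FOUNDERS,):
            raise SimulationError("cis effect vector must have 16 entries")


def simulate_expression(
    probs: FounderProbPanel,
    cis_genes: Sequence[CisGene],
    noise_sd: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-genotype expression = probability . effect + Gaussian noise.

    Returns ``(expression, truth)``: expression is genotypes x genes; truth
    records each planted effect vector in the standard eQTL-table layout
    (gene, chrom, bp, mean_A1..mean_B8, n_A1..n_B8) so it can feed the
    correlation machinery directly.
    """
    if noise_sd < 0:
        raise SimulationError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    expr = {}
    truth_rows = []
    for gene in cis_genes:
        idx = probs.position_index(gene.chrom, gene.bp)
        mu = probs.at(idx) @ gene.effects
        expr[gene.gene] = mu + rng.normal(0.0, noise_sd, probs.n_genotypes)
        row: dict = {"gene": gene.gene, "chrom": gene.chrom, "bp": gene.bp}
        for j, panel in enumerate(PANELS):
            for f in range(1, N_FOUNDERS + 1):
                row[f"mean_{panel}{f}"] = gene.effects[j * N_FOUNDERS + f - 1]
                row[f"n_{panel}{f}"] = probs.n_genotypes
        truth_rows.append(row)
    expression = pd.DataFrame(expr, index=pd.Index(probs.genotypes, name="genotype"))
    return expression, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# activity traces
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SleepArchitecture:
    """Two-state (wake/sleep) per-minute Markov parameters, by phase.

    ``p_onset_*``: P(wake -> start of a sleep run) per minute;
    ``p_wake_*``: P(sleep -> wake) per minute; ``rate_*``: mean beam breaks
    per awake minute (Poisson).  This is generative plumbing for the assayed
    behaviour, not a mechanistic sleep model.
    """

    p_onset_light: float = 0.05
    p_onset_dark: float = 0.12
    p_wake_light: float = 0.10
    p_wake_dark: float = 0.04
    rate_light: float = 2.5
    rate_dark: float = 2.0

    def __post_init__(self) -> None:
        for name in ("p_onset_light", "p_onset_dark", "p_wake_light", "p_wake_dark"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimulationError(f"{name}={v} outside [0, 1]")
        if self.rate_light < 0 or self.rate_dark < 0:
            raise SimulationError("activity rates must be >= 0")

    def onset(self, light: bool) -> float:
        return self.p_onset_light if light else self.p_onset_dark

    def wake(self, light: bool) -> float:
        return self.p_wake_light if light else self.p_wake_dark

    def rate(self, light: bool) -> float:
        return self.rate_light if light else self.rate_dark


def shift_architecture(
    base: SleepArchitecture, z: float, slope: float = 0.5, phase: str = "light"
) -> SleepArchitecture:
    """Genotype dependence: shift P(sleep->wake) by ``-slope*z`` on the logit
    scale in the given phase, so larger genetic values mean longer sleep."""
    def logit(p):  # clip away exact 0/1 which have no finite logit
        p = min(max(p, 1e-9), 1 - 1e-9)
        return math.log(p / (1 - p))

    def expit(x):
        return 1.0 / (1.0 + math.exp(-x))

    kw = {}
    for ph in ("light", "dark") if phase == "both" else (phase,):
        kw[f"p_wake_{ph}"] = expit(logit(getattr(base, f"p_wake_{ph}")) - slope * z)
    from dataclasses import replace

    return replace(base, **kw)


def simulate_dam(
    architectures: Sequence[SleepArchitecture] | SleepArchitecture,
    n_flies: int | None = None,
    n_days: int = 4,
    lights_on: str = "08:00",
    seed: int = 0,
    start_date: str = "2020-01-07",
    monitor: str = "M001",
) -> ActivityMatrix:
    """Simulate one monitor (up to 32 channels) of minute-binned activity.

    The recording starts at ``lights_on`` on ``start_date`` and runs for
    ``n_days`` 24 h periods under a 12h:12h photoperiod.  Minutes in the
    sleep state have count 0; awake minutes are Poisson with the phase's
    waking rate.  The initial state is drawn from the stationary
    distribution of the starting phase's chain.
    """
    if isinstance(architectures, SleepArchitecture):
        if n_flies is None:
            raise SimulationError("n_flies required with a single architecture")
        architectures = [architectures] * n_flies
    archs = list(architectures)
    if not 1 <= len(archs) <= N_CHANNELS:
        raise SimulationError(f"need 1..{N_CHANNELS} architectures per monitor")
    if n_days < 1:
        raise SimulationError("n_days must be >= 1")
    rng = np.random.default_rng(seed)
    t = n_days * 1440
    nf = len(archs)

    minute_of_phase = np.arange(t) % 1440
    light = (minute_of_phase < 720).astype(np.int64)  # recording starts lights-on

    onset = np.array([[a.onset(bool(l)) for a in archs] for l in (1, 0)])
    wake = np.array([[a.wake(bool(l)) for a in archs] for l in (1, 0)])
    rate = np.array([[a.rate(bool(l)) for a in archs] for l in (1, 0)])

    # stationary start in the initial phase
    p0, w0 = onset[0], wake[0]
    denom = p0 + w0
    p_sleep0 = np.where(denom > 0, p0 / np.where(denom > 0, denom, 1.0), 0.0)
    asleep = rng.random(nf) < p_sleep0

    counts = np.zeros((t, N_CHANNELS), dtype=np.int64)
    for i in range(t):
        row = 0 if light[i] else 1
        u = rng.random(nf)
        asleep = np.where(asleep, u >= wake[row], u < onset[row])
        awake = ~asleep
        c = np.zeros(nf, dtype=np.int64)
        if awake.any():
            c[awake] = rng.poisson(rate[row][awake])
        counts[i, :nf] = c

    hh, mm = (int(x) for x in lights_on.split(":"))
    start = pd.Timestamp(f"{start_date} {hh:02d}:{mm:02d}:00")
    timestamps = pd.date_range(start, periods=t, freq="min")
    return ActivityMatrix(
        timestamps=timestamps,
        counts=counts,
        light=light,
        status=np.ones(t, dtype=np.int64),
        monitor=monitor,
    )
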