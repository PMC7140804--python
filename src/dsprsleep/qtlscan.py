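"""Genome scans by regression of genotype means on founder probabilities.

At each grid position the genotype mean phenotype is regressed on the 16
additive founder probabilities (8 maternal pA + 8 paternal pB) with a
subpopulation covariate, and evidence is summarised as

    LOD = (n/2) * log10(RSS_null / RSS_full)

where the null model holds the intercept and covariates only.  Because each
panel's 8 probabilities sum to 1, the full design is rank deficient; the fit
drops the last column of each panel (equivalent, for RSS and hence LOD, to a
pseudo-inverse fit — the projection onto the column space is what matters,
and an orthonormal basis of that space is used throughout).

Genomewide significance is calibrated by permuting genotype means against
probability rows — by default within subpopulation, preserving the covariate
structure — and taking the empirical (1 - alpha) quantile of the
per-permutation genomewide maximum LOD.  Support intervals are 3-LOD drops
from the peak; QTL effect sizes are reported as the percentage of
among-genotype variance explained (PVE); founder effects are means over
genotypes hard-assigned to a founder (probability >= 0.95), reported only
when backed by at least ``min_obs`` genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg

from .simpanel import N_FOUNDERS, PANELS, FounderProbPanel

DEFAULT_ALPHAS = (0.01, 0.05, 0.10, 0.20)


class ScanError(ValueError):
    pass


def _orth(x: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the column space (rank-deficiency safe)."""
    q = linalg.orth(x)
    return q


def _align_phenotype(phenotypes, panel: FounderProbPanel, trait: str | None):
    """Return y ordered like ``panel.genotypes``; error on misalignment."""
    from .sleepmetrics import PhenotypeTable

    if isinstance(phenotypes, PhenotypeTable):
        if trait is None:
            raise ScanError("a trait name is required with a PhenotypeTable")
        series = phenotypes.trait_means(trait)
    elif isinstance(phenotypes, pd.Series):
        series = phenotypes
    else:
        series = pd.Series(np.asarray(phenotypes, dtype=float), index=panel.genotypes)
    missing = [g for g in panel.genotypes if g not in series.index]
    if missing:
        raise ScanError(
            f"{len(missing)} panel genotypes missing from phenotypes "
            f"(first: {missing[:3]})"
        )
    y = series.reindex(panel.genotypes).to_numpy(dtype=float)
    if len(y) < 2:
        raise ScanError("need at least 2 genotypes")
    # a constant phenotype is allowed and yields LOD = 0 everywhere
    return y


def _covariate_matrix(covariates, panel: FounderProbPanel) -> np.ndarray:
    """Covariate columns (no intercept).  The string ``"subpop"`` uses the
    panel's subpopulation labels as a single indicator column."""
    if covariates is None:
        return np.empty((panel.n_genotypes, 0))
    if isinstance(covariates, str):
        if covariates != "subpop":
            raise ScanError(f"unknown covariate shorthand {covariates!r}")
        return (panel.subpop == 2).astype(float)[:, None]
    arr = np.asarray(covariates, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.shape[0] != panel.n_genotypes:
        raise ScanError("covariate rows do not match panel genotypes")
    return arr


@dataclass
class ScanResult:
    """LOD curve over the grid for one trait."""

    trait: str
    grid: pd.DataFrame  # chrom, bp, cM
    lod: np.ndarray
    n: int
    thresholds: dict[float, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        out = self.grid.copy()
        out["lod"] = self.lod
        out["trait"] = self.trait
        return out

    def write_csv(self, path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, index=False, float_format="%.6g")
        return path


@dataclass
class QTLPeak:
    """A called QTL: peak, 3-LOD-drop support interval, effect summaries."""

    trait: str
    chrom: str
    peak_bp: int
    peak_cm: float
    peak_index: int
    lod: float
    lo_bp: int
    hi_bp: int
    lo_cm: float
    hi_cm: float
    pve: float | None = None
    founder_means: pd.DataFrame | None = None
    n: int | None = None

    @property
    def interval(self) -> tuple[str, int, int]:
        return (self.chrom, self.lo_bp, self.hi_bp)


class ScanEngine:
    """Shared machinery for scans and permutations on one (panel, covariate)
    pair.  Projection bases are recomputed per call; nothing large is cached
    beyond the null basis."""

    def __init__(self, panel: FounderProbPanel, covariates="subpop"):
        self.panel = panel
        self.covar = _covariate_matrix(covariates, panel)
        n = panel.n_genotypes
        self.x0 = np.column_stack([np.ones(n), self.covar])
        self.u0 = _orth(self.x0)
        k = panel.n_founders
        # drop the last probability column of each panel block (sums to 1)
        self.keep = np.r_[0 : k - 1, k : 2 * k - 1]
        self.n = n

    def _position_design(self, index: int) -> np.ndarray:
        return np.column_stack([self.x0, self.panel.at(index)[:, self.keep]])

    @staticmethod
    def _rss(u: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Residual sums of squares of y (vector or matrix of columns)
        projected off the span of the orthonormal basis ``u``."""
        yy = np.sum(np.square(y), axis=0)
        proj = u.T @ y
        return np.maximum(yy - np.sum(np.square(proj), axis=0), 0.0)

    def lod_curve(self, y: np.ndarray) -> np.ndarray:
        rss0 = float(self._rss(self.u0, y))
        lod = np.zeros(self.panel.n_positions)
        if rss0 == 0.0:
            return lod
        for p in range(self.panel.n_positions):
            rss = float(self._rss(_orth(self._position_design(p)), y))
            rss = max(rss, 1e-12 * rss0)
            lod[p] = 0.5 * self.n * np.log10(rss0 / rss)
        return np.maximum(lod, 0.0)

    def max_lod(self, y_matrix: np.ndarray) -> np.ndarray:
        """Genomewide maximum LOD for each column of ``y_matrix``."""
        rss0 = self._rss(self.u0, y_matrix)
        rss0 = np.where(rss0 > 0, rss0, np.inf)
        best = np.zeros(y_matrix.shape[1])
        for p in range(self.panel.n_positions):
            rss = self._rss(_orth(self._position_design(p)), y_matrix)
            rss = np.maximum(rss, 1e-12 * np.where(np.isfinite(rss0), rss0, 1.0))
            np.maximum(best, 0.5 * self.n * np.log10(rss0 / rss), out=best)
        return best

    def rss_at(self, index: int, y: np.ndarray):
        """(RSS_null, RSS_full, rank_null, rank_full) at one position."""
        u1 = _orth(self._position_design(index))
        rss0 = float(self._rss(self.u0, y))
        rss1 = float(self._rss(u1, y))
        return rss0, rss1, self.u0.shape[1], u1.shape[1]


def scan_trait(
    phenotypes,
    panel: FounderProbPanel,
    covariates="subpop",
    trait: str | None = None,
) -> ScanResult:
    """LOD genome scan of one trait's genotype means."""
    y = _align_phenotype(phenotypes, panel, trait)
    engine = ScanEngine(panel, covariates)
    return ScanResult(
        trait=trait or getattr(phenotypes, "name", None) or "trait",
        grid=panel.grid.copy(),
        lod=engine.lod_curve(y),
        n=panel.n_genotypes,
    )


def permutation_thresholds(
    phenotypes,
    panel: FounderProbPanel,
    covariates="subpop",
    n_perm: int = 1000,
    alphas: Sequence[float] = DEFAULT_ALPHAS,
    seed: int = 0,
    trait: str | None = None,
    stratify: bool = True,
    return_null: bool = False,
):
    """Permutation genomewide thresholds.

    Genotype means are shuffled against probability rows, within
    subpopulation when ``stratify`` (default) so the covariate structure is
    preserved; ``threshold(alpha)`` is the empirical (1 - alpha) quantile of
    the per-permutation genomewide maximum LOD.
    """
    alphas = tuple(alphas)
    if any(not 0.0 < a <= 1.0 for a in alphas):
        raise ScanError("alphas must lie in (0, 1]")
    if any(a <= 0.05 for a in alphas) and n_perm < 100:
        raise ScanError("n_perm must be >= 100 for alpha <= 0.05")
    y = _align_phenotype(phenotypes, panel, trait)
    engine = ScanEngine(panel, covariates)
    rng = np.random.default_rng(seed)

    strata = (
        [np.flatnonzero(panel.subpop == s) for s in np.unique(panel.subpop)]
        if stratify
        else [np.arange(panel.n_genotypes)]
    )
    ymat = np.empty((panel.n_genotypes, n_perm))
    for j in range(n_perm):
        yj = y.copy()
        for idx in strata:
            yj[idx] = yj[rng.permutation(idx)]
        ymat[:, j] = yj
    null_max = engine.max_lod(ymat)
    thresholds = {a: float(np.quantile(null_max, 1.0 - a)) for a in alphas}
    if return_null:
        return thresholds, null_max
    return thresholds


def support_interval(
    scan: ScanResult, peak_index: int, drop: float = 3.0
) -> tuple[int, int]:
    """Indices [lo, hi] of the drop-LOD support interval around a peak.

    Boundaries sit at the first grid position, walking outward, where the
    LOD falls *strictly* below ``peak - drop`` (a plateau exactly at
    ``peak - drop`` stays inside); clipped at chromosome ends.
    """
    chrom = scan.grid["chrom"].iloc[peak_index]
    on_chrom = np.flatnonzero((scan.grid["chrom"] == chrom).to_numpy())
    lo_end, hi_end = int(on_chrom[0]), int(on_chrom[-1])
    cutoff = scan.lod[peak_index] - drop
    lo = peak_index
    while lo > lo_end and not scan.lod[lo - 1] < cutoff:
        lo -= 1
    if lo > lo_end:
        lo -= 1
    hi = peak_index
    while hi < hi_end and not scan.lod[hi + 1] < cutoff:
        hi += 1
    if hi < hi_end:
        hi += 1
    return lo, hi


def founder_means(
    panel: FounderProbPanel,
    position_index: int,
    phenotypes,
    assign_threshold: float = 0.95,
    min_obs: int = 10,
    trait: str | None = None,
) -> pd.DataFrame:
    """Founder haplotype means at one position.

    Each genotype is hard-assigned, per panel, to the founder whose
    probability is >= ``assign_threshold`` (no such founder: unassigned).
    Means backed by fewer than ``min_obs`` genotypes are omitted.  Columns:
    panel, founder, mean, n.
    """
    y = _align_phenotype(phenotypes, panel, trait)
    probs = panel.at(position_index)
    k = panel.n_founders
    rows = []
    for j, pname in enumerate(PANELS):
        block = probs[:, j * k : (j + 1) * k]
        best = np.argmax(block, axis=1)
        assigned = block[np.arange(len(best)), best] >= assign_threshold
        for f in range(k):
            sel = assigned & (best == f)
            n = int(sel.sum())
            if n >= min_obs:
                rows.append(
                    {
                        "panel": pname,
                        "founder": f + 1,
                        "mean": float(y[sel].mean()),
                        "n": n,
                    }
                )
    return pd.DataFrame(rows, columns=["panel", "founder", "mean", "n"])


def variance_explained(
    phenotypes,
    panel: FounderProbPanel,
    position_index: int,
    covariates="subpop",
    trait: str | None = None,
    adjusted: bool = True,
) -> float:
    """PVE (%) at a position, relative to the covariate-only null.

    The raw ratio ``100 * (RSS_null - RSS_full) / RSS_null`` overstates the
    effect of the 14 founder predictors by roughly ``k/n`` even under the
    null, so by default the residual variances are degree-of-freedom
    adjusted (``1 - s2_full/s2_null``); ``adjusted=False`` gives the raw
    ratio.
    """
    y = _align_phenotype(phenotypes, panel, trait)
    engine = ScanEngine(panel, covariates)
    rss0, rss1, k0, k1 = engine.rss_at(position_index, y)
    if rss0 == 0.0:
        raise ScanError("null model fits perfectly; PVE undefined")
    if not adjusted:
        return 100.0 * (rss0 - rss1) / rss0
    n = engine.n
    if n - k1 <= 0:
        raise ScanError("no residual degrees of freedom at this position")
    s2_full = rss1 / (n - k1)
    s2_null = rss0 / (n - k0)
    return float(np.clip(100.0 * (1.0 - s2_full / s2_null), 0.0, 100.0))


def call_peaks(
    scan: ScanResult,
    threshold: float,
    panel: FounderProbPanel | None = None,
    phenotypes=None,
    covariates="subpop",
    drop: float = 3.0,
    assign_threshold: float = 0.95,
    min_obs: int = 10,
    trait: str | None = None,
) -> list[QTLPeak]:
    """Call QTL: local maxima above ``threshold``; maxima whose support
    intervals overlap are merged into a single QTL (highest LOD wins)."""
    lod = scan.lod
    peaks: list[QTLPeak] = []
    for chrom in scan.grid["chrom"].unique():
        idx = np.flatnonzero((scan.grid["chrom"] == chrom).to_numpy())
        sub = lod[idx]
        cand = []
        for j in range(len(idx)):
            left = sub[j - 1] if j > 0 else -np.inf
            right = sub[j + 1] if j + 1 < len(idx) else -np.inf
            if sub[j] > threshold and sub[j] >= left and sub[j] > right:
                cand.append(idx[j])
        cand.sort(key=lambda i: -lod[i])
        accepted: list[tuple[int, int, int]] = []
        for i in cand:
            lo, hi = support_interval(scan, i, drop=drop)
            if any(lo <= h and l <= hi for _, l, h in accepted):
                continue
            accepted.append((i, lo, hi))
        for i, lo, hi in sorted(accepted, key=lambda t: t[0]):
            row = scan.grid.iloc[i]
            peak = QTLPeak(
                trait=scan.trait,
                chrom=chrom,
                peak_bp=int(row["bp"]),
                peak_cm=float(row["cM"]),
                peak_index=int(i),
                lod=float(lod[i]),
                lo_bp=int(scan.grid["bp"].iloc[lo]),
                hi_bp=int(scan.grid["bp"].iloc[hi]),
                lo_cm=float(scan.grid["cM"].iloc[lo]),
                hi_cm=float(scan.grid["cM"].iloc[hi]),
                n=scan.n,
            )
            if panel is not None and phenotypes is not None:
                peak.pve = variance_explained(
                    phenotypes, panel, i, covariates=covariates, trait=trait
                )
                peak.founder_means = founder_means(
                    panel,
                    i,
                    phenotypes,
                    assign_threshold=assign_threshold,
                    min_obs=min_obs,
                    trait=trait,
                )
            peaks.append(peak)
    return peaks


def peaks_to_frame(peaks: Sequence[QTLPeak]) -> pd.DataFrame:
    rows = []
    for p in peaks:
        rows.append(
            {
                "trait": p.trait,
                "chrom": p.chrom,
                "peak_bp": p.peak_bp,
                "peak_cm": round(p.peak_cm, 4),
                "lod": round(p.lod, 4),
                "lo_bp": p.lo_bp,
                "hi_bp": p.hi_bp,
                "pve_pct": None if p.pve is None else round(p.pve, 3),
                "n": p.n,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "trait", "chrom", "peak_bp", "peak_cm", "lod",
            "lo_bp", "hi_bp", "pve_pct", "n",
        ],
    )
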