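"""QTL groups, founder-effect correlations, and expression integration.

Trait-specific QTL whose 3-LOD-drop support intervals overlap (closed
intervals; touching counts) are merged into "QTL groups" — the connected
components of the interval-overlap graph per chromosome.  A group's interval
is the mutual intersection of its members' intervals when that is non-empty;
for chain-overlap topologies where members overlap pairwise but share no
common region, the fallback is the minimal interval covering all pairwise
overlap regions, and the rule used is recorded per group.

Founder-effect similarity between two QTL (or between a QTL and a cis-eQTL)
is the Pearson correlation of founder haplotype means over the founders
estimated on both sides with at least ``min_obs`` genotypes each; fewer than
3 shared founders yields no result.  Expression-phenotype correlations are
screened per trait at a Benjamini-Hochberg FDR.

Intervals are stored 1-based inclusive (genome-browser convention); BED
exports convert to 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .qtlscan import QTLPeak
from .simpanel import N_FOUNDERS, PANELS


class GroupError(ValueError):
    pass


@dataclass
class QTLGroup:
    group_id: str
    members: list[QTLPeak]
    chrom: str
    lo: int
    hi: int
    rule: str  # "single" | "intersection" | "overlap-span"

    @property
    def traits(self) -> list[str]:
        return sorted({m.trait for m in self.members})

    @property
    def size_bp(self) -> int:
        return self.hi - self.lo + 1


@dataclass
class CorrelationResult:
    pair: str
    r: float
    p: float
    n: int


def merge_qtl(peaks: Sequence[QTLPeak]) -> list[QTLGroup]:
    """Connected components of the per-chromosome interval-overlap graph."""
    ordered = sorted(peaks, key=lambda p: (p.chrom, p.lo_bp, p.hi_bp, p.trait))
    groups: list[QTLGroup] = []
    components: list[list[QTLPeak]] = []
    current: list[QTLPeak] = []
    reach = None
    last_chrom = None
    for p in ordered:
        if current and (p.chrom != last_chrom or p.lo_bp > reach):
            components.append(current)
            current = []
        if not current:
            reach = p.hi_bp
        else:
            reach = max(reach, p.hi_bp)
        current.append(p)
        last_chrom = p.chrom
    if current:
        components.append(current)

    for i, comp in enumerate(components, start=1):
        if len(comp) == 1:
            lo, hi, rule = comp[0].lo_bp, comp[0].hi_bp, "single"
        else:
            lo = max(m.lo_bp for m in comp)
            hi = min(m.hi_bp for m in comp)
            if lo <= hi:
                rule = "intersection"
            else:
                spans = [
                    (max(a.lo_bp, b.lo_bp), min(a.hi_bp, b.hi_bp))
                    for ai, a in enumerate(comp)
                    for b in comp[ai + 1 :]
                    if max(a.lo_bp, b.lo_bp) <= min(a.hi_bp, b.hi_bp)
                ]
                lo = min(s for s, _ in spans)
                hi = max(e for _, e in spans)
                rule = "overlap-span"
        groups.append(
            QTLGroup(
                group_id=f"QG{i}",
                members=list(comp),
                chrom=comp[0].chrom,
                lo=lo,
                hi=hi,
                rule=rule,
            )
        )
    return groups


def groups_to_frame(groups: Sequence[QTLGroup]) -> pd.DataFrame:
    """Summary table: one row per group (id, phenotype codes, chrom,
    interval, size in Mb, membership rule)."""
    rows = []
    for g in groups:
        rows.append(
            {
                "group": g.group_id,
                "phenotypes": ";".join(g.traits),
                "chrom": g.chrom,
                "lo_bp": g.lo,
                "hi_bp": g.hi,
                "size_mb": round(g.size_bp / 1e6, 4),
                "n_members": len(g.members),
                "rule": g.rule,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "group", "phenotypes", "chrom", "lo_bp", "hi_bp",
            "size_mb", "n_members", "rule",
        ],
    )


def groups_to_bed(groups: Sequence[QTLGroup], path) -> Path:
    """Write group intervals as BED (0-based, half-open)."""
    path = Path(path)
    lines = [f"{g.chrom}\t{g.lo - 1}\t{g.hi}\t{g.group_id}" for g in groups]
    path.write_text("\n".join(lines) + ("\n" if lines else ""))
    return path


# ---------------------------------------------------------------------------
# founder-effect correlations
# ---------------------------------------------------------------------------

def correlate_founder_effects(
    means_a: pd.DataFrame,
    means_b: pd.DataFrame,
    min_obs: int = 10,
    pair: str = "",
) -> CorrelationResult | None:
    """Pearson correlation of two sets of founder means.

    Each table has columns panel, founder, mean, n.  Only founders present
    on both sides with n >= ``min_obs`` on each enter; fewer than 3 shared
    founders returns None.
    """
    a = means_a[means_a["n"] >= min_obs]
    b = means_b[means_b["n"] >= min_obs]
    merged = a.merge(b, on=["panel", "founder"], suffixes=("_a", "_b"))
    if len(merged) < 3:
        return None
    x = merged["mean_a"].to_numpy(dtype=float)
    y = merged["mean_b"].to_numpy(dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        return None
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(pair=pair, r=float(r), p=float(p), n=len(merged))


def eqtl_table_means(row: pd.Series) -> pd.DataFrame:
    """Founder-mean table for one eQTL record (mean_A1..mean_B8 / n_* columns)."""
    rows = []
    for panel in PANELS:
        for f in range(1, N_FOUNDERS + 1):
            mcol, ncol = f"mean_{panel}{f}", f"n_{panel}{f}"
            if mcol in row and pd.notna(row[mcol]):
                rows.append(
                    {
                        "panel": panel,
                        "founder": f,
                        "mean": float(row[mcol]),
                        "n": int(row[ncol]) if ncol in row else 0,
                    }
                )
    return pd.DataFrame(rows, columns=["panel", "founder", "mean", "n"])


def eqtl_qtl_correlations(
    groups: Sequence[QTLGroup],
    eqtl_table: pd.DataFrame,
    min_obs: int = 10,
) -> pd.DataFrame:
    """Founder-effect correlations between trait QTL and overlapping cis-eQTL.

    One row per (trait-specific member QTL, cis-eQTL gene inside the group
    interval).  Nominal p-values are reported alongside a Bonferroni flag
    over all emitted pairs; no multiplicity adjustment is applied to the
    nominal column.
    """
    rows = []
    for g in groups:
        sel = (
            (eqtl_table["chrom"] == g.chrom)
            & (eqtl_table["bp"] >= g.lo)
            & (eqtl_table["bp"] <= g.hi)
        )
        for _, gene_row in eqtl_table[sel].iterrows():
            gene_means = eqtl_table_means(gene_row)
            for member in g.members:
                if member.founder_means is None:
                    continue
                res = correlate_founder_effects(
                    member.founder_means,
                    gene_means,
                    min_obs=min_obs,
                    pair=f"{g.group_id}:{member.trait}~{gene_row['gene']}",
                )
                if res is None:
                    continue
                rows.append(
                    {
                        "group": g.group_id,
                        "trait": member.trait,
                        "gene": gene_row["gene"],
                        "r": res.r,
                        "p": res.p,
                        "n_founders": res.n,
                    }
                )
    out = pd.DataFrame(
        rows, columns=["group", "trait", "gene", "r", "p", "n_founders"]
    )
    if len(out):
        out["sig_nominal"] = out["p"] < 0.05
        out["sig_bonferroni"] = out["p"] < 0.05 / len(out)
    else:
        out["sig_nominal"] = pd.Series(dtype=bool)
        out["sig_bonferroni"] = pd.Series(dtype=bool)
    return out


# ---------------------------------------------------------------------------
# expression-phenotype correlations
# ---------------------------------------------------------------------------

def pearson_r_p(x: np.ndarray, y_matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r of ``x`` against each column of ``y_matrix``, with two-sided
    p from the t-distribution transform t = r*sqrt((n-2)/(1-r^2))."""
    n = len(x)
    if n < 3:
        raise GroupError("need at least 3 observations for a correlation")
    xs = (x - x.mean()) / x.std()
    ys = y_matrix - y_matrix.mean(axis=0)
    sd = ys.std(axis=0)
    sd = np.where(sd > 0, sd, np.nan)
    r = (xs @ (ys / sd)) / n
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    return r, p


def expression_phenotype_correlations(
    expression: pd.DataFrame,
    phenotypes,
    traits: Sequence[str] | None = None,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Per-trait gene-expression screens under BH FDR control.

    ``expression`` is genotypes x genes.  For each trait the genotype means
    are correlated with every gene across shared genotypes; BH is applied
    within trait at level ``fdr``.  Returns trait, gene, r, p, q,
    significant.
    """
    from .sleepmetrics import PhenotypeTable

    if isinstance(phenotypes, PhenotypeTable):
        trait_list = traits or phenotypes.traits
        getter = phenotypes.trait_means
    else:  # DataFrame: genotype index, trait columns
        trait_list = traits or list(phenotypes.columns)
        getter = lambda t: phenotypes[t]  # noqa: E731

    frames = []
    for trait in trait_list:
        y = getter(trait)
        shared = expression.index.intersection(y.index)
        if len(shared) < 3:
            raise GroupError(f"<3 shared genotypes for trait {trait}")
        x = y.loc[shared].to_numpy(dtype=float)
        mat = expression.loc[shared].to_numpy(dtype=float)
        r, p = pearson_r_p(x, mat)
        ok = ~np.isnan(p)
        q = np.full_like(p, np.nan)
        sig = np.zeros_like(ok)
        if ok.any():
            rej, qv, _, _ = multipletests(p[ok], alpha=fdr, method="fdr_bh")
            q[ok] = qv
            sig[ok] = rej
        frames.append(
            pd.DataFrame(
                {
                    "trait": trait,
                    "gene": expression.columns,
                    "r": r,
                    "p": p,
                    "q": q,
                    "significant": sig.astype(bool),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
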