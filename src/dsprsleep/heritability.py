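"""Broad-sense heritability from per-fly replicate data.

The model is ``y = mu + subpop + genotype(subpop) + e`` with genotype random
and subpopulation fixed:

    H^2 = sigma2_genotype / (sigma2_genotype + sigma2_residual)

i.e. the repeatability of genotype values within subpopulation.  Because the
mapping panel is fully inbred-derived, the among-genotype variance is the
total genetic variance, so this ratio is broad-sense heritability.
Subpopulation variance is excluded from both numerator and denominator by
default (the subpopulation contrast is a design covariate, not segregating
variation); ``subpop="random"`` instead estimates it as a variance
component and reports it, still leaving it out of H^2.

Two estimation paths are provided:

* ``method="reml"`` — linear mixed model (statsmodels MixedLM), valid for
  unbalanced data;
* ``method="moments"`` — nested-ANOVA expected mean squares, balanced
  designs only, with negative estimates truncated at zero.  This closed-form
  path doubles as an independent cross-check of the REML fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


class HeritabilityError(ValueError):
    pass


@dataclass
class VarianceComponents:
    trait: str
    sigma2_subpop: float | None
    sigma2_genotype: float
    sigma2_residual: float
    h2: float
    n_genotypes: int
    n_flies: int
    method: str
    subpop_treatment: str  # "fixed" | "random"

    def to_dict(self) -> dict:
        return {
            "trait": self.trait,
            "sigma2_subpop": self.sigma2_subpop,
            "sigma2_genotype": self.sigma2_genotype,
            "sigma2_residual": self.sigma2_residual,
            "h2": self.h2,
            "n_genotypes": self.n_genotypes,
            "n_flies": self.n_flies,
            "method": self.method,
            "subpop_treatment": self.subpop_treatment,
        }


def _validate(df: pd.DataFrame) -> None:
    for col in ("genotype", "subpop", "value"):
        if col not in df.columns:
            raise HeritabilityError(f"per-fly table missing column {col!r}")
    counts = df.groupby("genotype")["value"].size()
    if len(counts) < 2:
        raise HeritabilityError("need at least 2 genotypes")
    if (counts >= 2).sum() < 2:
        raise HeritabilityError("need replication (>=2 flies) in >=2 genotypes")


def _moments(df: pd.DataFrame) -> tuple[float, float]:
    """Nested-ANOVA expected-mean-square estimators (balanced designs).

    With genotypes nested in subpopulation and n flies per genotype:
    E[MS_geno(subpop)] = sigma2_e + n*sigma2_g, E[MS_error] = sigma2_e.
    """
    counts = df.groupby("genotype")["value"].size()
    n = int(counts.iloc[0])
    if counts.nunique() != 1 or n < 2:
        raise HeritabilityError(
            "moments path requires a balanced design with >=2 flies/genotype"
        )
    ss_g = 0.0
    df_g = 0
    ss_e = 0.0
    df_e = 0
    for _, sub in df.groupby("subpop"):
        geno_means = sub.groupby("genotype")["value"].mean()
        sp_mean = sub["value"].mean()
        ss_g += n * float(((geno_means - sp_mean) ** 2).sum())
        df_g += len(geno_means) - 1
        for _, g in sub.groupby("genotype"):
            ss_e += float(((g["value"] - g["value"].mean()) ** 2).sum())
            df_e += len(g) - 1
    if df_g < 1 or df_e < 1:
        raise HeritabilityError("degenerate design for moments estimator")
    ms_g = ss_g / df_g
    ms_e = ss_e / df_e
    sigma2_g = max((ms_g - ms_e) / n, 0.0)
    return sigma2_g, ms_e


def _reml(df: pd.DataFrame, subpop: str) -> tuple[float | None, float, float]:
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    data = df[["genotype", "subpop", "value"]].copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if subpop == "fixed":
            model = smf.mixedlm("value ~ C(subpop)", data, groups=data["genotype"])
            fit = model.fit(reml=True)
            return None, float(fit.cov_re.iloc[0, 0]), float(fit.scale)
        # subpop as an (outer) variance component
        model = sm.MixedLM.from_formula(
            "value ~ 1",
            data,
            groups=data["subpop"],
            vc_formula={"genotype": "0 + C(genotype)"},
            re_formula="1",
        )
        fit = model.fit(reml=True)
        s2_sub = float(fit.cov_re.iloc[0, 0])
        s2_g = float(fit.vcomp[0])
        return s2_sub, s2_g, float(fit.scale)


def estimate_h2(
    per_fly: pd.DataFrame,
    trait: str | None = None,
    method: str = "reml",
    subpop: str = "fixed",
) -> VarianceComponents:
    """Estimate broad-sense heritability for one trait from per-fly data.

    ``per_fly`` needs columns genotype, subpop, value (and trait when the
    table is long over several traits).
    """
    df = per_fly
    if trait is not None and "trait" in df.columns:
        df = df[df["trait"] == trait]
    df = df.dropna(subset=["value"])
    _validate(df)
    if method not in ("reml", "moments"):
        raise HeritabilityError(f"unknown method {method!r}")
    if subpop not in ("fixed", "random"):
        raise HeritabilityError(f"subpop must be 'fixed' or 'random'")

    if method == "moments":
        if subpop == "random":
            raise HeritabilityError("moments path treats subpopulation as fixed")
        s2_sub = None
        s2_g, s2_e = _moments(df)
    else:
        s2_sub, s2_g, s2_e = _reml(df, subpop)

    denom = s2_g + s2_e
    h2 = s2_g / denom if denom > 0 else 0.0
    return VarianceComponents(
        trait=trait or "trait",
        sigma2_subpop=s2_sub,
        sigma2_genotype=s2_g,
        sigma2_residual=s2_e,
        h2=float(np.clip(h2, 0.0, 1.0)),
        n_genotypes=df["genotype"].nunique(),
        n_flies=len(df),
        method=method,
        subpop_treatment=subpop,
    )
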