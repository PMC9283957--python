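"""Trait summary statistics, ANOVA variance components with narrow-sense
heritability, and across-environment BLUP line values.

Heritability uses the entry-mean basis standard for multi-environment line
trials: h2 = sG2 / (sG2 + sGE2/nE + se2/(nE nR)).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class TraitSummary:
    n: int
    min: float
    max: float
    mean: float
    se: float
    sd: float
    variance: float
    kurtosis: float  # excess, bias-adjusted
    skewness: float  # bias-adjusted
    cv_percent: float


def cv_percent(mean: float, sd: float) -> float:
    """Coefficient of variation, 100 * SD / mean."""
    if mean == 0:
        return float("nan")
    return 100.0 * sd / mean


def summarize_trait(values) -> TraitSummary:
    """Moments of a trait vector: SD and variance with ddof = 1, SE = SD /
    sqrt(n), CV = 100 SD / mean, bias-adjusted sample skewness and excess
    kurtosis (undefined for constant input, reported as NaN)."""
    x = pd.Series(np.asarray(values, dtype=float)).dropna()
    n = int(x.size)
    if n < 2:
        raise ValueError("need at least 2 non-missing values")
    sd = float(x.std(ddof=1))
    mean = float(x.mean())
    return TraitSummary(
        n=n,
        min=float(x.min()),
        max=float(x.max()),
        mean=mean,
        se=sd / math.sqrt(n),
        sd=sd,
        variance=sd**2,
        kurtosis=float(x.kurt()) if sd > 0 else float("nan"),
        skewness=float(x.skew()) if sd > 0 else float("nan"),
        cv_percent=0.0 if sd == 0 else cv_percent(mean, sd),
    )


# --------------------------------------------------------------------------
# variance components
# --------------------------------------------------------------------------


@dataclass
class VarianceComponents:
    sigma_g2: float
    sigma_ge2: float
    sigma_e2: float
    n_env: int
    n_rep: int
    h2: float
    p_genotype: float
    p_environment: float
    method: str  # "ems" or "reml"
    truncated: bool = False  # any negative estimate floored at 0


def _entry_mean_h2(sg2: float, sge2: float, se2: float, ne: int, nr: int) -> float:
    denom = sg2 + sge2 / ne + se2 / (ne * nr)
    return sg2 / denom if denom > 0 else float("nan")


def _is_balanced(df: pd.DataFrame) -> tuple[bool, int]:
    counts = df.groupby(["individual", "environment"], observed=True).size()
    full = counts.index.get_level_values(0).nunique() * counts.index.get_level_values(1).nunique()
    return counts.nunique() == 1 and counts.size == full, int(counts.iloc[0])


def anova_varcomp(pheno: pd.DataFrame) -> VarianceComponents:
    """Variance components of the genotype x environment random model.

    Balanced designs are solved by the expected-mean-squares equations
    (se2 = MS_error; sGE2 = (MS_GE - MS_error)/nR; sG2 = (MS_G - MS_GE)/
    (nE nR)); unbalanced designs fall back to REML on the same model.
    F-tests for the genotype and environment main effects use MS_GE as the
    denominator.  With a single replicate per cell, G x E and error are
    confounded: sGE2 is reported as 0 and the residual absorbs both.
    """
    df = pheno.dropna(subset=["value"]).copy()
    genos = df["individual"].unique()
    envs = df["environment"].unique()
    ng, ne = len(genos), len(envs)
    if ng < 2 or ne < 2:
        raise ValueError("need >= 2 genotypes and >= 2 environments")
    balanced, nr = _is_balanced(df)

    if balanced:
        cell = df.groupby(["individual", "environment"], observed=True)["value"]
        cell_mean = cell.mean().unstack()  # ng x ne
        grand = df["value"].mean()
        g_mean = cell_mean.mean(axis=1)
        e_mean = cell_mean.mean(axis=0)
        ss_g = ne * nr * float(((g_mean - grand) ** 2).sum())
        ss_e = ng * nr * float(((e_mean - grand) ** 2).sum())
        inter = cell_mean.sub(g_mean, axis=0).sub(e_mean, axis=1) + grand
        ss_ge = nr * float((inter**2).to_numpy().sum())
        ss_tot = float(((df["value"] - grand) ** 2).sum())
        ss_err = max(ss_tot - ss_g - ss_e - ss_ge, 0.0)
        df_g, df_e, df_ge = ng - 1, ne - 1, (ng - 1) * (ne - 1)
        df_err = ng * ne * (nr - 1)
        ms_g, ms_e, ms_ge = ss_g / df_g, ss_e / df_e, ss_ge / df_ge
        ms_err = ss_err / df_err if df_err > 0 else 0.0
        if nr > 1:
            se2 = ms_err
            sge2 = (ms_ge - ms_err) / nr
            sg2 = (ms_g - ms_ge) / (ne * nr)
        else:
            se2 = ms_ge  # confounded with G x E
            sge2 = 0.0
            sg2 = (ms_g - ms_ge) / ne
        truncated = sge2 < 0 or sg2 < 0
        sge2, sg2 = max(sge2, 0.0), max(sg2, 0.0)
        p_g = float(stats.f.sf(ms_g / ms_ge, df_g, df_ge)) if ms_ge > 0 else 0.0
        p_e = float(stats.f.sf(ms_e / ms_ge, df_e, df_ge)) if ms_ge > 0 else 0.0
        method = "ems"
    else:
        sg2, sge2, se2, p_g, p_e, truncated = _reml_varcomp(df)
        nr = max(int(round(len(df) / (ng * ne))), 1)
        method = "reml"

    h2 = _entry_mean_h2(sg2, sge2, se2, ne, nr)
    return VarianceComponents(
        sigma_g2=float(sg2), sigma_ge2=float(sge2), sigma_e2=float(se2),
        n_env=ne, n_rep=nr, h2=float(np.clip(h2, 0.0, 1.0)),
        p_genotype=p_g, p_environment=p_e, method=method, truncated=truncated,
    )


def _reml_varcomp(df: pd.DataFrame):
    """REML fit of value ~ env (fixed) + genotype (random) + genotype:env
    (random) via a mixed linear model with a variance component per cell."""
    import statsmodels.formula.api as smf

    d = df.rename(columns={"individual": "geno", "environment": "env"})
    d["cell"] = d["geno"].astype(str) + ":" + d["env"].astype(str)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(
            "value ~ C(env)", d, groups="geno", re_formula="1",
            vc_formula={"ge": "0 + C(cell)"},
        )
        fit = model.fit(reml=True)
    sg2 = float(fit.cov_re.iloc[0, 0])
    sge2 = float(fit.vcomp[0]) if len(fit.vcomp) else 0.0
    se2 = float(fit.scale)
    # main-effect p-values from a balanced-style ANOVA on cell means
    cell_mean = d.groupby(["geno", "env"], observed=True)["value"].mean().unstack()
    ng, ne = cell_mean.shape
    grand = float(np.nanmean(cell_mean.to_numpy()))
    g_dev = cell_mean.mean(axis=1) - grand
    e_dev = cell_mean.mean(axis=0) - grand
    inter = cell_mean.sub(cell_mean.mean(axis=1), axis=0).sub(cell_mean.mean(axis=0), axis=1) + grand
    ms_g = ne * float((g_dev**2).sum()) / (ng - 1)
    ms_e = ng * float((e_dev**2).sum()) / (ne - 1)
    ms_ge = float(np.nansum(inter.to_numpy() ** 2)) / ((ng - 1) * (ne - 1))
    p_g = float(stats.f.sf(ms_g / ms_ge, ng - 1, (ng - 1) * (ne - 1))) if ms_ge > 0 else 0.0
    p_e = float(stats.f.sf(ms_e / ms_ge, ne - 1, (ng - 1) * (ne - 1))) if ms_ge > 0 else 0.0
    return max(sg2, 0.0), max(sge2, 0.0), se2, p_g, p_e, (sg2 < 0 or sge2 < 0)


# --------------------------------------------------------------------------
# BLUP line values
# --------------------------------------------------------------------------


def blup_lines(pheno: pd.DataFrame) -> pd.Series:
    """Across-environment BLUP of each line from the random-intercept model
    value = mu + env + line + eps.

    Environment effects are removed as fixed effects; each line's adjusted
    mean deviation is shrunk by lambda_i = sL2 / (sL2 + se2 / n_i) and added
    back to the grand intercept.  Returns mu + BLUP per line.
    """
    df = pheno.dropna(subset=["value"]).copy()
    if len(df) < 2:
        raise ValueError("need more than one observation")
    if df["environment"].nunique() < 2:
        raise ValueError("BLUP across environments needs >= 2 environments")
    grand = float(df["value"].mean())
    env_eff = df.groupby("environment", observed=True)["value"].mean() - grand
    df["adj"] = df["value"] - df["environment"].map(env_eff).astype(float)

    # one-way variance components on the environment-adjusted values
    lines = df.groupby("individual", observed=True)["adj"]
    n_i = lines.size()
    means = lines.mean()
    ss_within = float(((df["adj"] - df["individual"].map(means)) ** 2).sum())
    n_tot, k = len(df), len(means)
    df_within = n_tot - k
    se2 = ss_within / df_within if df_within > 0 else 0.0
    ss_between = float((n_i * (means - grand) ** 2).sum())
    ms_between = ss_between / (k - 1)
    n0 = (n_tot - float((n_i**2).sum()) / n_tot) / (k - 1)
    sl2 = max((ms_between - se2) / n0, 0.0)

    if sl2 == 0.0:
        lam = pd.Series(0.0, index=means.index)
    else:
        lam = sl2 / (sl2 + se2 / n_i)
    blup = grand + lam * (means - grand)
    blup.name = "blup"
    return blup
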