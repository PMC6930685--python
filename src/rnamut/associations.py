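"""Covariate regressions on mutation load and expression associations.

Mutation counts per sample are driven first by technical factors
(sequencing depth, transcriptome Shannon diversity, fixative time, ischemic
time, RNA integrity); their effect is removed by a per-tissue OLS and all
biology is read off the residuals. Biological factors (sex, age, BMI,
genotype PCs) are then tested by multiple regression plus independent
Spearman correlations and, for sex, a two-sided Mann-Whitney contrast.

Per-gene expression associations fit, for every sufficiently expressed gene,

    load_i = b0 + sum_n b_n cov_n,i + gamma * x_i

with load and expression inverse-normal transformed (Blom offsets) and
covariates {PC1-3, age, sex, BMI}. Three empirical FDR estimators support
the gene-, pathway- and cross-tissue-level scans.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

TECHNICAL_COVARIATES = ["seq_depth", "shannon_diversity", "pax_time", "ischemic_time", "rin"]
BIOLOGICAL_COVARIATES = ["sex", "age", "bmi", "pc1", "pc2", "pc3"]
EXPRESSION_COVARIATES = ["pc1", "pc2", "pc3", "age", "sex", "bmi"]


def inverse_normal_transform(values: Sequence[float]) -> np.ndarray:
    """Rank-based mapping to standard normal quantiles (Blom offsets).

    Ties receive average ranks; the transform is invariant to any strictly
    monotone transform of the input.
    """
    x = np.asarray(values, dtype=float)
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - 3.0 / 8.0) / (len(x) + 0.25))


def _check_design(X: pd.DataFrame) -> None:
    design = sm.add_constant(X.to_numpy(dtype=float), has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        corr = X.corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        pair = corr.stack().idxmax() if len(X.columns) > 1 else (X.columns[0],) * 2
        raise ValueError(f"singular design: {pair[0]} and {pair[1]} are collinear")


@dataclass
class TechnicalFit:
    residuals: pd.Series
    coefficients: pd.DataFrame  # coef, p per covariate


def residualize_technical(counts: pd.Series, meta: pd.DataFrame) -> TechnicalFit:
    """Remove technical structure from per-sample mutation counts by OLS.

    Regressors: sequencing depth, Shannon diversity, fixative time,
    ischemic time and RNA integrity. Returns residuals plus the coefficient
    table with per-covariate p values.
    """
    samples = counts.index
    X = meta.set_index("sample").loc[samples, TECHNICAL_COVARIATES].astype(float)
    if len(samples) < len(TECHNICAL_COVARIATES) + 2:
        raise ValueError(
            f"need >= {len(TECHNICAL_COVARIATES) + 2} samples, got {len(samples)}"
        )
    _check_design(X)
    model = sm.OLS(counts.to_numpy(dtype=float), sm.add_constant(X)).fit()
    coef = pd.DataFrame(
        {"coef": model.params, "se": model.bse, "p": model.pvalues}
    ).drop(index="const")
    residuals = pd.Series(model.resid.to_numpy(), index=samples)
    return TechnicalFit(residuals, coef)


@dataclass
class BiologicalAssociations:
    regression: pd.DataFrame  # coef, p per factor
    spearman: pd.DataFrame  # rho, p per factor
    sex_mwu_p: float | None
    skipped: list[str] = field(default_factory=list)


def biological_associations(residuals: pd.Series, meta: pd.DataFrame) -> BiologicalAssociations:
    """Biological factors vs technical-residualized mutation load.

    Multiple regression on sex, age, BMI and genotype PCs 1-3 with
    per-coefficient p values; independent Spearman correlations per factor;
    and a two-sided Mann-Whitney sex contrast. Constant factors (e.g. sex in
    a single-sex tissue) are skipped and listed.
    """
    samples = residuals.index
    X = meta.set_index("sample").loc[samples, BIOLOGICAL_COVARIATES].astype(float)
    skipped = [c for c in X.columns if X[c].nunique() <= 1]
    X = X.drop(columns=skipped)
    y = residuals.to_numpy(dtype=float)
    if X.empty:
        raise ValueError("all biological covariates are constant")
    _check_design(X)
    model = sm.OLS(y, sm.add_constant(X)).fit()
    regression = pd.DataFrame(
        {"coef": model.params, "se": model.bse, "p": model.pvalues}
    ).drop(index="const")

    sp_rows = {}
    for c in X.columns:
        rho, p = stats.spearmanr(X[c].to_numpy(), y)
        sp_rows[c] = {"rho": rho, "p": p}
    spearman = pd.DataFrame.from_dict(sp_rows, orient="index")

    sex_p = None
    if "sex" not in skipped:
        sex = meta.set_index("sample").loc[samples, "sex"].to_numpy()
        g0, g1 = y[sex == 0], y[sex == 1]
        if len(g0) and len(g1):
            sex_p = float(stats.mannwhitneyu(g0, g1, alternative="two-sided").pvalue)
    return BiologicalAssociations(regression, spearman, sex_p, skipped)


def bh_fdr_across(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p values (used across tissues per factor)."""
    return multipletests(np.asarray(p_values, dtype=float), method="fdr_bh")[1]


@dataclass
class AssociationResult:
    gene: str
    gamma: float
    se: float
    p: float
    n: int
    bonferroni_p: float | None = None


def expression_association(
    load_residuals: pd.Series,
    expression: pd.DataFrame,
    meta: pd.DataFrame,
    tpm_min: float = 1.0,
    frac_min: float = 0.20,
    transform: str = "blom",
) -> tuple[list[AssociationResult], list[str]]:
    """Per-gene expression vs mutation-load association scan for one tissue.

    Only genes with TPM > ``tpm_min`` in at least ``frac_min`` of samples
    are tested. Response and expression are inverse-normal transformed
    (``transform="blom"``, the default) or used in original units
    (``transform="none"``, which preserves effect-size scale); the OLS
    includes PC1-3, age, sex and BMI; the gamma p value is the coefficient
    t test; Bonferroni correction is per tissue (over the genes tested
    here). Returns (results, genes skipped by the expression filter).
    """
    if transform not in ("blom", "none"):
        raise ValueError(f"unknown transform {transform!r}")
    samples = list(load_residuals.index)
    expr = expression[samples]
    covs = meta.set_index("sample").loc[samples, EXPRESSION_COVARIATES].astype(float)
    cov_cols = [c for c in covs.columns if covs[c].nunique() > 1]
    covs = covs[cov_cols]
    y_raw = load_residuals.to_numpy(dtype=float)
    y = inverse_normal_transform(y_raw) if transform == "blom" else y_raw

    results: list[AssociationResult] = []
    skipped: list[str] = []
    for gene in expr.index:
        x_raw = expr.loc[gene].to_numpy(dtype=float)
        if np.mean(x_raw > tpm_min) < frac_min or np.unique(x_raw).size <= 1:
            skipped.append(gene)
            continue
        x = inverse_normal_transform(x_raw) if transform == "blom" else x_raw
        X = covs.copy()
        X["expression"] = x
        model = sm.OLS(y, sm.add_constant(X)).fit()
        results.append(
            AssociationResult(
                gene=gene,
                gamma=float(model.params["expression"]),
                se=float(model.bse["expression"]),
                p=float(model.pvalues["expression"]),
                n=len(samples),
            )
        )
    m = len(results)
    for r in results:
        r.bonferroni_p = min(1.0, r.p * m)
    return results, skipped


def fdr_gene_tissue(target_p: float, genomewide_p: Sequence[float]) -> float:
    """Empirical FDR of one gene-tissue association.

    The fraction of all tested genes in the same scan with an equal or
    lower p value than the target.
    """
    ps = np.asarray(genomewide_p, dtype=float)
    if ps.size == 0:
        raise ValueError("empty genome-wide p-value vector")
    return float(np.mean(ps <= target_p))


def fdr_permutation(
    original_p: Sequence[float],
    permuted_p: Sequence[float],
    threshold: float,
) -> float | None:
    """Permutation-ratio FDR at a p-value threshold.

    (fraction of permuted p <= threshold) / (fraction of original p <=
    threshold), capped at 1. E.g. 0.1 % of permuted vs 1 % of original tests
    below threshold gives 10 %. Returns None (undefined) when no original p
    reaches the threshold. The same estimator serves the pathway-level and
    the cross-tissue per-gene schemes.
    """
    orig = np.asarray(original_p, dtype=float)
    perm = np.asarray(permuted_p, dtype=float)
    frac_orig = float(np.mean(orig <= threshold)) if orig.size else 0.0
    if frac_orig == 0.0:
        return None
    frac_perm = float(np.mean(perm <= threshold)) if perm.size else 0.0
    return min(1.0, frac_perm / frac_orig)


def permuted_gene_groups(
    all_genes: Sequence[str],
    group_size: int,
    n_groups: int = 10000,
    seed: int = 0,
) -> list[list[str]]:
    """Random same-size gene groups for the permutation-FDR schemes."""
    genes = list(all_genes)
    if group_size > len(genes):
        raise ValueError("group size exceeds the number of genes")
    rng = np.random.default_rng(seed)
    return [
        list(rng.choice(genes, size=group_size, replace=False)) for _ in range(n_groups)
    ]
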