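"""Expression-corrected exon mutation rates vs histone-mark signals.

Exon mutation counts scale with sequencing depth (expression). Exons are
assigned to 100 equal-count depth bins and the bin median is subtracted
from each exon's observed count, leaving a depth-corrected rate. The
corrected rate is then regressed jointly on the five histone-mark signals
(H3K36me3, H3K4me1, H3K4me3, H3K27me3, H3K9me3); per-mark partial effects
come from regressing the rate on the residual of that mark against the
other four.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

HISTONE_MARKS = ["H3K36me3", "H3K4me1", "H3K4me3", "H3K27me3", "H3K9me3"]


def corrected_exon_rates(
    depths: pd.Series,
    mutation_counts: pd.Series,
    n_bins: int = 100,
) -> tuple[pd.Series, pd.Series]:
    """Depth-corrected mutation rate per exon.

    Exons are ranked by sequencing depth into ``n_bins`` left-closed
    equal-count percentile bins (ties broken by stable input order); the
    corrected rate is observed count minus the bin median. Returns
    (corrected rates, bin index per exon).
    """
    if len(depths) != len(mutation_counts):
        raise ValueError("depths and counts must align")
    n = len(depths)
    if n < n_bins:
        raise ValueError(
            f"{n} exons cannot fill {n_bins} bins; use a smaller n_bins"
        )
    order = np.argsort(depths.to_numpy(dtype=float), kind="stable")
    bin_idx = np.empty(n, dtype=int)
    bin_idx[order] = np.minimum((np.arange(n) * n_bins) // n, n_bins - 1)
    bins = pd.Series(bin_idx, index=depths.index)
    counts = mutation_counts.astype(float)
    medians = counts.groupby(bins).median()
    corrected = counts - bins.map(medians)
    return corrected, bins


@dataclass
class HistoneRegressionResult:
    coefficients: pd.DataFrame  # coef, p per mark (joint model)
    partial_r2: pd.Series  # per mark
    joint_r2: float


def histone_regression(
    corrected_rates: pd.Series,
    mark_signals: pd.DataFrame,
) -> HistoneRegressionResult:
    """Joint and partial associations of histone marks with mutation rate.

    The joint OLS uses all five marks as features, giving per-coefficient p
    values. Each mark's partial r^2 residualizes that mark on the other
    four, then regresses the rate on the residual — the variance the mark
    explains beyond the rest.
    """
    marks = [m for m in HISTONE_MARKS if m in mark_signals.columns]
    if len(marks) < 2:
        raise ValueError(f"need at least two histone marks, got {marks}")
    X = mark_signals.loc[corrected_rates.index, marks].astype(float)
    if len(X) < len(marks) + 2:
        raise ValueError("too few exons for the regression")
    corr = X.corr().abs()
    np.fill_diagonal(corr.values, 0.0)
    if (corr > 0.9999).any().any():
        pair = corr.stack().idxmax()
        raise ValueError(f"collinear marks: {pair[0]} and {pair[1]}")
    y = corrected_rates.to_numpy(dtype=float)
    joint = sm.OLS(y, sm.add_constant(X)).fit()
    coefficients = pd.DataFrame(
        {"coef": joint.params, "se": joint.bse, "p": joint.pvalues}
    ).drop(index="const")

    partial = {}
    for m in marks:
        others = [o for o in marks if o != m]
        resid = sm.OLS(X[m].to_numpy(), sm.add_constant(X[others])).fit().resid
        fit = sm.OLS(y, sm.add_constant(np.asarray(resid))).fit()
        partial[m] = float(fit.rsquared)
    return HistoneRegressionResult(
        coefficients, pd.Series(partial), float(joint.rsquared)
    )


def read_exon_signals(path: str) -> pd.DataFrame:
    """Read a per-exon signal TSV (exon id plus five mark-mean columns)."""
    df = pd.read_csv(path, sep="\t")
    if "exon" not in df.columns:
        raise ValueError(f"{path}: missing 'exon' column")
    missing = [m for m in HISTONE_MARKS if m not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mark columns {missing}")
    return df.set_index("exon")
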