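"""Core vs non-core comparisons and cross-organism correlations.

Group means are compared with Welch's unequal-variance t-test (the
appropriate two-sample test when core and accessory genes need not share
a variance); expression enters on a log10(RPKM) scale with zero
expression floored at RPKM 0.01.  Cross-organism agreement of core-gene
attributes is summarized by pairwise Pearson correlations reported as
R^2 with significance stars.  No multiple-testing correction is applied;
raw p-values are reported against alpha 0.05.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "welch_t",
    "log10_rpkm",
    "core_vs_noncore_table",
    "core_correlations",
    "significance_stars",
]

FACTORS = ("expression_log10_rpkm", "gc_fraction", "cai", "length_bp")

RPKM_FLOOR = 0.01


def welch_t(x, y) -> dict[str, float]:
    """Welch's two-sample t-test (unequal variances), two-sided.

    Returns the t statistic, Welch-Satterthwaite degrees of freedom and
    the two-sided p-value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 observations")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        if x.mean() == y.mean():
            return {"t": 0.0, "df": float(len(x) + len(y) - 2), "p": 1.0}
        raise ValueError("zero variance in both groups with unequal means")
    res = stats.ttest_ind(x, y, equal_var=False)
    se2 = vx / len(x) + vy / len(y)
    df = se2**2 / (
        (vx / len(x)) ** 2 / (len(x) - 1) + (vy / len(y)) ** 2 / (len(y) - 1)
    )
    return {"t": float(res.statistic), "df": float(df), "p": float(res.pvalue)}


def log10_rpkm(values, floor: float = RPKM_FLOOR) -> np.ndarray:
    """log10 of RPKM with zeros floored so the transform is finite."""
    values = np.asarray(values, dtype=float)
    return np.log10(np.maximum(values, floor))


def core_vs_noncore_table(
    per_organism: dict[str, pd.DataFrame],
    core_gene_ids: dict[str, set[str]],
    factors: tuple[str, ...] = FACTORS,
) -> pd.DataFrame:
    """Per organism x factor, compare core-member genes with the rest.

    ``per_organism`` maps organism label to a gene-level frame with
    columns gene_id, mean_rpkm, gc_fraction, cai, length_bp;
    ``core_gene_ids`` maps organism label to the gene ids belonging to
    core families there.  Expression is compared on log10(mean RPKM).
    """
    rows = []
    for org, df in per_organism.items():
        core_ids = core_gene_ids.get(org, set())
        if not core_ids:
            raise ValueError(f"{org}: empty core gene set")
        is_core = df["gene_id"].isin(core_ids).to_numpy()
        work = df.copy()
        work["expression_log10_rpkm"] = log10_rpkm(work["mean_rpkm"].to_numpy())
        for factor in factors:
            x = work.loc[~is_core, factor].to_numpy(dtype=float)
            y = work.loc[is_core, factor].to_numpy(dtype=float)
            test = welch_t(x, y)
            rows.append(
                {
                    "organism": org,
                    "factor": factor,
                    "noncore_mean": float(x.mean()),
                    "core_mean": float(y.mean()),
                    "t_statistic": test["t"],
                    "df": test["df"],
                    "p_value": test["p"],
                }
            )
    return pd.DataFrame(rows)


def significance_stars(p: float) -> str:
    if p < 0.0001:
        return "***"
    if p < 0.001:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def core_correlations(
    attribute: str, per_organism_values: dict[str, pd.Series]
) -> pd.DataFrame:
    """Pairwise Pearson correlations of a per-cluster attribute.

    ``per_organism_values`` maps organism label to a Series indexed by
    cluster id.  Each pair is correlated over the clusters with finite
    values in both organisms (at least 3 required); the result is a
    long-format frame with R^2, two-sided p, n and significance stars.
    """
    if len(per_organism_values) < 2:
        raise ValueError("need at least 2 organisms")
    rows = []
    for org1, org2 in itertools.combinations(sorted(per_organism_values), 2):
        a = per_organism_values[org1]
        b = per_organism_values[org2]
        joined = pd.concat([a, b], axis=1, join="inner", keys=["a", "b"]).dropna()
        joined = joined[np.isfinite(joined).all(axis=1)]
        n = len(joined)
        if n < 3:
            raise ValueError(f"{org1}/{org2}: fewer than 3 shared finite values")
        r, p = stats.pearsonr(joined["a"], joined["b"])
        rows.append(
            {
                "org1": org1,
                "org2": org2,
                "attribute": attribute,
                "r2": float(r**2),
                "p_value": float(p),
                "n": n,
                "stars": significance_stars(float(p)),
            }
        )
    return pd.DataFrame(rows)


def normalized_location(midpoints, genome_length: int) -> np.ndarray:
    """Gene midpoint as a fraction of genome length, in [0, 1)."""
    arr = np.asarray(midpoints, dtype=float) / float(genome_length)
    return np.mod(arr, 1.0)
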