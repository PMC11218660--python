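"""Active-enhancer calling: a negative-binomial two-condition test.

RNA and DNA libraries are treated as two experimental conditions paired
within replicates.  Per design, counts are modeled with a NB log-linear
model (replicate fixed effects + a material effect) on median-of-ratios
normalized libraries; the material coefficient is tested with a two-sided
Wald test and Benjamini-Hochberg correction across designs.  A design is
active when padj < 0.05 and the RNA/DNA log2 fold change is positive.

Dispersion is a pooled method-of-moments estimate with a floor rather than
the shrinkage machinery of full count-model toolkits; calibration is
checked by simulation instead of bit-matching any reference tool.  To keep
the Wald test honest at typical replicate numbers (a handful of libraries
per design), p-values use a t reference distribution with the model's
residual degrees of freedom rather than a normal.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

ALPHA_FLOOR = 0.01
PADJ_CUTOFF = 0.05


def count_matrix(counts: pd.DataFrame) -> pd.DataFrame:
    """Long counts (design_id, replicate, material, count) to a wide matrix
    with one column per library (replicate, material)."""
    wide = counts.pivot_table(index="design_id", columns=["replicate", "material"],
                              values="count", aggfunc="first").fillna(0)
    wide.columns = [f"rep{r}_{m}" for r, m in wide.columns]
    return wide


def size_factors(matrix: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library scaling factors.

    factor_j = median over all-nonzero designs of count_ij / geometric
    mean_i.  Falls back to total-count scaling (normalized to mean 1) with a
    warning when no design is nonzero in every library.
    """
    vals = matrix.to_numpy(float)
    nonzero = (vals > 0).all(axis=1)
    if not nonzero.any():
        warnings.warn("no design with nonzero counts in all libraries; "
                      "falling back to total-count size factors")
        totals = vals.sum(axis=0)
        return pd.Series(totals / totals.mean(), index=matrix.columns)
    sub = vals[nonzero]
    log_geo = np.log(sub).mean(axis=1, keepdims=True)
    ratios = sub / np.exp(log_geo)
    return pd.Series(np.median(ratios, axis=0), index=matrix.columns)


def estimate_dispersion(matrix: pd.DataFrame, factors: pd.Series,
                        materials: pd.Series,
                        alpha_floor: float = ALPHA_FLOOR) -> pd.Series:
    """Per-design method-of-moments dispersion on normalized counts.

    Residual variance is pooled across the two materials after removing
    each material's mean; alpha = max((s^2 - mu) / mu^2, alpha_floor) with
    mu the grand mean of normalized counts.
    """
    norm = matrix.to_numpy(float) / factors.to_numpy(float)
    groups = materials.reindex(matrix.columns).to_numpy()
    resid = np.empty_like(norm)
    n_groups = 0
    for g in np.unique(groups):
        cols = groups == g
        if cols.sum() < 2:
            raise ValueError("dispersion estimation needs >=2 replicates per material")
        resid[:, cols] = norm[:, cols] - norm[:, cols].mean(axis=1, keepdims=True)
        n_groups += 1
    s2 = (resid ** 2).sum(axis=1) / max(norm.shape[1] - n_groups, 1)
    mu = norm.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (s2 - mu) / mu ** 2
    alpha = np.where(np.isfinite(alpha), alpha, alpha_floor)
    return pd.Series(np.maximum(alpha, alpha_floor), index=matrix.index)


def library_materials(matrix: pd.DataFrame) -> pd.Series:
    """Material (DNA/RNA) of each library column, parsed from its name."""
    return pd.Series([c.rsplit("_", 1)[1] for c in matrix.columns],
                     index=matrix.columns)


def _design_matrix(columns: list[str]) -> tuple[np.ndarray, int]:
    """Intercept + replicate dummies + RNA indicator; returns (X, rna_col)."""
    reps = [c.rsplit("_", 1)[0] for c in columns]
    mats = [c.rsplit("_", 1)[1] for c in columns]
    uniq = sorted(set(reps))
    X = [np.ones(len(columns))]
    for r in uniq[1:]:
        X.append(np.array([1.0 if x == r else 0.0 for x in reps]))
    X.append(np.array([1.0 if m == "RNA" else 0.0 for m in mats]))
    return np.column_stack(X), len(X) - 1


def test_active(matrix: pd.DataFrame, factors: pd.Series | None = None,
                dispersions: pd.Series | None = None,
                alpha_floor: float = ALPHA_FLOOR,
                padj_cutoff: float = PADJ_CUTOFF) -> pd.DataFrame:
    """NB Wald test of RNA vs DNA enrichment for every design.

    Returns a frame with log2fc, wald_stat, p, padj and the ``active`` flag
    (padj < cutoff and log2fc > 0).  Designs whose fit fails to converge are
    flagged with p = 1.
    """
    if factors is None:
        factors = size_factors(matrix)
    if dispersions is None:
        dispersions = estimate_dispersion(matrix, factors,
                                          library_materials(matrix), alpha_floor)
    X, rna_col = _design_matrix(list(matrix.columns))
    offset = np.log(factors.to_numpy(float))
    # t reference with the dispersion-estimate degrees of freedom,
    # n_libraries - n_materials = 2(k-1): the dominant small-sample noise in
    # the Wald statistic is the method-of-moments dispersion, and a plain
    # normal reference is anti-conservative at a handful of replicates.
    n_materials = len({c.rsplit("_", 1)[1] for c in matrix.columns})
    df_wald = max(X.shape[0] - n_materials, 1)
    rows = []
    for design_id, y in matrix.iterrows():
        alpha = float(dispersions.loc[design_id])
        converged = True
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.GLM(y.to_numpy(float), X,
                             family=sm.families.NegativeBinomial(alpha=alpha),
                             offset=offset).fit(maxiter=100)
            beta = fit.params[rna_col]
            se = fit.bse[rna_col]
            converged = bool(fit.converged) and np.isfinite(se) and se > 0
        except Exception:
            converged = False
        if not converged:
            rows.append((design_id, 0.0, 0.0, 1.0, False))
            continue
        wald = beta / se
        p = 2.0 * stats.t.sf(abs(wald), df_wald)
        rows.append((design_id, beta / np.log(2.0), wald, p, True))
    out = pd.DataFrame(rows, columns=["design_id", "log2fc", "wald_stat", "p",
                                      "converged"]).set_index("design_id")
    out["padj"] = multipletests(out["p"], method="fdr_bh")[1]
    out["active"] = (out["padj"] < padj_cutoff) & (out["log2fc"] > 0)
    return out.reset_index()


def call_active(counts: pd.DataFrame, alpha_floor: float = ALPHA_FLOOR,
                padj_cutoff: float = PADJ_CUTOFF,
                keep: pd.Series | None = None) -> pd.DataFrame:
    """End-to-end calling from a long count table.

    ``keep`` optionally restricts testing to coverage-filtered designs.
    """
    matrix = count_matrix(counts)
    if keep is not None:
        matrix = matrix.loc[matrix.index.intersection(keep[keep].index)]
    return test_active(matrix, alpha_floor=alpha_floor, padj_cutoff=padj_cutoff)
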