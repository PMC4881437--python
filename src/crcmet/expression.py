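"""Expression meta-cohort assembly and candidate-gene validation.

Datasets are merged on their common genes and standardized per dataset and
gene to mean 0 / unit variance (an exact location/scale batch correction;
adequate here because every downstream statistic is rank- or
regression-based). Candidate genes from the CNA funnel are then screened:
univariate Cox fits of OS and DFS on standardized expression, a
direction-consistency rule (a deleted gene should show worse outcome at low
expression, i.e. a negative coefficient; an amplified gene a positive one),
a stringent p < 0.005 cut, tumor-vs-normal and clinicopathological
association tests, quartile stratification, and the combination analysis of
jointly underexpressed deleted genes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .survival import cox_fit, kaplan_meier, logrank_test


def standardize_by_batch(expr: pd.DataFrame, batches: pd.Series) -> pd.DataFrame:
    """Center/scale each gene within each batch (mean 0, unit variance,
    ddof=1). Genes constant within a batch become NaN there."""
    out = expr.copy().astype(float)
    for b in batches.unique():
        cols = batches.index[batches == b]
        block = out[cols]
        sd = block.std(axis=1, ddof=1)
        out[cols] = block.sub(block.mean(axis=1), axis=0).div(sd.replace(0, np.nan), axis=0)
    return out


def assemble_meta_cohort(datasets: list[tuple[pd.DataFrame, pd.Series]]):
    """Merge >=2 (expression, batch-label) datasets into one standardized
    meta-cohort restricted to the shared genes.

    Returns (matrix, batch labels). Raises if the gene intersection is empty.
    """
    if len(datasets) < 2:
        raise ValueError("need at least 2 datasets")
    common = datasets[0][0].index
    for df, _ in datasets[1:]:
        common = common.intersection(df.index)
    if len(common) == 0:
        raise ValueError("datasets share no genes")
    parts, labels = [], []
    for df, batch in datasets:
        parts.append(df.loc[common])
        labels.append(batch)
    expr = pd.concat(parts, axis=1)
    batches = pd.concat(labels)
    return standardize_by_batch(expr, batches), batches


def mannwhitney_test(values_a, values_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U; exact enumeration for small tie-free
    samples (combined n < 20), tie-corrected normal approximation otherwise."""
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([a, b])
    if np.ptp(combined) == 0:
        return float(len(a) * len(b) / 2), 1.0
    ties = len(np.unique(combined)) < len(combined)
    method = "exact" if (len(combined) < 20 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def _association_pvalues(values: np.ndarray, meta: pd.DataFrame) -> dict:
    out = {}
    tumor = meta["tissue"] == "tumor"
    if tumor.any() and (~tumor).any():
        out["tumor_vs_normal_p"] = mannwhitney_test(values[tumor], values[~tumor])[1]
    else:
        out["tumor_vs_normal_p"] = np.nan
    for col in ("msi", "grade", "stage"):
        sub = meta.loc[tumor]
        groups = [
            values[np.asarray(sub.index[sub[col] == g])]
            for g in sub[col].dropna().unique()
            if g != "" and (sub[col] == g).sum() >= 2
        ]
        if len(groups) >= 2:
            out[f"{col}_p"] = float(stats.kruskal(*groups).pvalue)
        else:
            out[f"{col}_p"] = np.nan
    return out


def screen_gene(
    gene: str,
    expr: pd.DataFrame,
    meta: pd.DataFrame,
    direction: str,
    alpha: float = 0.05,
) -> dict:
    """Screen one candidate gene against the meta-cohort.

    Cox OS and DFS are fit on standardized continuous expression over tumor
    samples with survival data. The gene passes the primary screen iff some
    endpoint has p < alpha AND that endpoint's coefficient sign matches the
    CNA direction (loss -> negative, gain -> positive).
    """
    if gene not in expr.index:
        raise KeyError(f"gene {gene} not in matrix")
    meta = meta.reset_index(drop=True)
    values = expr.loc[gene, meta["sample_id"]].to_numpy(float)
    surv = meta["tissue"].eq("tumor") & meta["dfs_time"].notna() & meta["os_time"].notna()
    if surv.sum() < 20:
        raise ValueError("need >=20 tumor samples with survival data")
    x = values[surv]
    x = (x - x.mean()) / x.std(ddof=1)
    fits = {}
    for ep in ("os", "dfs"):
        fits[ep] = cox_fit(x, meta.loc[surv, f"{ep}_time"], meta.loc[surv, f"{ep}_event"])
    want = -1.0 if direction == "loss" else 1.0
    passes = any(
        f.p < alpha and np.sign(f.coef) == want for f in fits.values()
    )
    rec = {
        "symbol": gene,
        "direction": direction,
        "cox_os_coef": fits["os"].coef,
        "cox_os_p": fits["os"].p,
        "cox_dfs_coef": fits["dfs"].coef,
        "cox_dfs_p": fits["dfs"].p,
        "primary_pass": bool(passes),
        "stringent_flag": min(fits["os"].p, fits["dfs"].p) < 0.005,
    }
    rec.update(_association_pvalues(values, meta))
    return rec


def screen_genes(
    candidates: pd.DataFrame, expr: pd.DataFrame, meta: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Screen a (symbol, direction) table; genes absent from the matrix or
    failing preconditions are recorded with a note and NaN statistics."""
    rows = []
    for _, c in candidates.drop_duplicates("symbol").iterrows():
        try:
            rows.append(screen_gene(c["symbol"], expr, meta, c["direction"], alpha))
        except (KeyError, ValueError, RuntimeError) as err:
            rows.append({"symbol": c["symbol"], "direction": c["direction"], "note": str(err)})
    return pd.DataFrame(rows)


def stringent_filter(candidates: pd.DataFrame, alpha: float = 0.005) -> pd.DataFrame:
    """Keep genes with min(Cox OS p, Cox DFS p) < alpha."""
    best = candidates[["cox_os_p", "cox_dfs_p"]].min(axis=1)
    return candidates[best < alpha].reset_index(drop=True)


def quartile_stratify(values: pd.Series) -> pd.Series:
    """Assign Q1..Q4 by the 25th/50th/75th percentile cut points
    (linear-interpolation quantiles); boundary ties go to the lower quartile."""
    v = values.astype(float)
    if v.nunique() == 1:
        raise ValueError("quartiles undefined for a constant gene")
    if len(v) < 4:
        raise ValueError("need >=4 samples")
    q25, q50, q75 = np.quantile(v.to_numpy(), [0.25, 0.5, 0.75])
    labels = np.where(
        v <= q25, "Q1", np.where(v <= q50, "Q2", np.where(v <= q75, "Q3", "Q4"))
    )
    return pd.Series(labels, index=values.index, name=values.name)


def combo_survival(
    genes: list[str],
    expr: pd.DataFrame,
    meta: pd.DataFrame,
    endpoint: str = "dfs",
) -> dict:
    """Joint-underexpression survival analysis for a set of deleted genes.

    Group A: samples where *every* listed gene sits in its own Q1 (joint
    underexpression). Group B: samples where every listed gene is in Q2-Q4.
    Samples mixing the two are excluded. Returns the log-rank comparison and
    the two KM curves.
    """
    if len(genes) < 1:
        raise ValueError("need at least one gene")
    meta = meta.reset_index(drop=True)
    tumor = meta[meta["tissue"] == "tumor"].dropna(subset=[f"{endpoint}_time"])
    quart = pd.DataFrame(
        {g: quartile_stratify(expr.loc[g, tumor["sample_id"]]) for g in genes}
    )
    all_q1 = (quart == "Q1").all(axis=1).to_numpy()
    none_q1 = (quart != "Q1").all(axis=1).to_numpy()
    if not all_q1.any():
        raise ValueError(
            "no sample jointly underexpresses all listed genes; "
            "use fewer genes or a larger cohort"
        )
    t = tumor[f"{endpoint}_time"].to_numpy(float)
    e = tumor[f"{endpoint}_event"].to_numpy(int)
    stat, p = logrank_test(t[all_q1], e[all_q1], t[none_q1], e[none_q1])
    return {
        "genes": list(genes),
        "endpoint": endpoint,
        "n_joint_q1": int(all_q1.sum()),
        "n_rest": int(none_q1.sum()),
        "logrank_stat": stat,
        "logrank_p": p,
        "km_joint_q1": kaplan_meier(t[all_q1], e[all_q1]),
        "km_rest": kaplan_meier(t[none_q1], e[none_q1]),
    }
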