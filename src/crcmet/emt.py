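"""Single-sample epithelial-mesenchymal transition (EMT) scoring.

The score places each tumor on a phenotype axis from -1 (fully epithelial)
to +1 (fully mesenchymal). The pipeline is: (1) a rank-enrichment phenotype
pre-score orders samples by mesenchymal character from curated epithelial /
mesenchymal gene sets; (2) the extreme tails of that ordering define
phenotype labels from which cohort-specific signatures are re-derived,
keeping genes whose observed between-tail fold change exceeds every one of
``n_perm`` label-permutation values (empirical q = 0) and whose ROC AUC for
tail membership clears a threshold; (3) per-sample enrichment of each
signature is computed by a single-sample, rank-based running-sum statistic
(ssGSEA: weighted in-set ECDF minus out-of-set ECDF, integrated over all
ranks); (4) the EMT score is the difference of the cohort min-max
normalized mesenchymal and epithelial enrichments, hence always in [-1, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score


@dataclass
class GeneSetPair:
    epithelial: list[str]
    mesenchymal: list[str]

    def __post_init__(self) -> None:
        if not self.epithelial or not self.mesenchymal:
            raise ValueError("both gene sets must be non-empty")
        dup = set(self.epithelial) & set(self.mesenchymal)
        if dup:
            raise ValueError(f"gene sets must be disjoint; shared: {sorted(dup)[:5]}")


def read_gmt(path) -> dict[str, list[str]]:
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def ssgsea_es(values: pd.Series, gene_set, weight_exponent: float = 0.25) -> float:
    """Single-sample enrichment score of ``gene_set`` in one sample.

    Genes are ranked by descending expression; the in-set ECDF is weighted
    by rank-normalized expression raised to ``weight_exponent`` (exponent 0
    gives unit weights, making the score a pure rank statistic); the
    out-of-set ECDF is unweighted. The score is the sum of the running
    difference over all ranks — positive when set genes concentrate at the
    top of the sample's ranking.
    """
    if values.index.has_duplicates:
        raise ValueError("duplicate gene symbols in expression vector")
    in_set = values.index.isin(set(gene_set))
    n, ns = len(values), int(in_set.sum())
    if ns == 0:
        raise ValueError(f"gene set has no overlap with measured genes: {list(gene_set)[:5]}")
    if ns == n:
        raise ValueError("gene set covers every measured gene; out-of-set ECDF undefined")
    order = np.argsort(-values.to_numpy(), kind="stable")
    hit = in_set[order]
    rank_norm = (np.arange(n, 0, -1) / n) ** weight_exponent
    w = np.where(hit, rank_norm, 0.0)
    p_in = np.cumsum(w) / w.sum()
    p_out = np.cumsum(~hit) / (n - ns)
    return float(np.sum(p_in - p_out))


def phenotype_prescore(
    expr: pd.DataFrame, curated: GeneSetPair, weight_exponent: float = 0.25
) -> pd.Series:
    """Preliminary per-sample mesenchymal probability in [0, 1].

    The raw statistic is es(mesenchymal) - es(epithelial) per sample,
    rank-scaled across the cohort (1 = most mesenchymal). It only needs to
    *order* samples for extreme-tail selection.
    """
    raw = pd.Series(
        {
            s: ssgsea_es(expr[s], curated.mesenchymal, weight_exponent)
            - ssgsea_es(expr[s], curated.epithelial, weight_exponent)
            for s in expr.columns
        }
    )
    n = len(raw)
    if n < 2:
        raise ValueError("prescore needs >=2 samples")
    return (raw.rank(method="average") - 1) / (n - 1)


def refine_signatures(
    expr: pd.DataFrame,
    prescores: pd.Series,
    extreme_fraction: float = 0.25,
    roc_min: float = 0.85,
    n_perm: int = 1000,
    seed: int = 0,
) -> GeneSetPair:
    """Re-derive cohort-specific E/M signatures from extreme-phenotype tails.

    The top ``extreme_fraction`` of samples by prescore are labelled
    mesenchymal-like, the bottom fraction epithelial-like. A gene enters a
    signature when (a) its observed between-tail mean difference exceeds in
    magnitude every one of ``n_perm`` label-permutation differences
    (SAM-like empirical q = 0), and (b) its ROC AUC for tail membership is
    >= roc_min (mesenchymal) or <= 1 - roc_min (epithelial); assignment
    follows the sign of the difference.
    """
    n = len(prescores)
    k = int(round(extreme_fraction * n))
    if k < 8:
        raise ValueError("need >=8 samples per extreme tail")
    order = prescores.sort_values(kind="stable")
    epi_samples = order.index[:k]
    mes_samples = order.index[-k:]
    X = expr[list(epi_samples) + list(mes_samples)].to_numpy(float)
    labels = np.concatenate([np.zeros(k), np.ones(k)])  # 1 = mesenchymal tail
    obs = X[:, k:].mean(axis=1) - X[:, :k].mean(axis=1)

    rng = np.random.default_rng(seed)
    max_null = np.zeros(X.shape[0])
    for _ in range(n_perm):
        perm = rng.permutation(2 * k)
        diff = X[:, perm[k:]].mean(axis=1) - X[:, perm[:k]].mean(axis=1)
        max_null = np.maximum(max_null, np.abs(diff))
    sam_pass = np.abs(obs) > max_null

    auc = np.array([roc_auc_score(labels, X[i]) for i in range(X.shape[0])])
    mes_genes = expr.index[(obs > 0) & sam_pass & (auc >= roc_min)].tolist()
    epi_genes = expr.index[(obs < 0) & sam_pass & (auc <= 1 - roc_min)].tolist()
    if not mes_genes or not epi_genes:
        raise ValueError(
            "no genes survived signature refinement; relax roc_min or "
            "extreme_fraction, or reduce n_perm"
        )
    return GeneSetPair(epithelial=epi_genes, mesenchymal=mes_genes)


def emt_score(
    expr: pd.DataFrame, signatures: GeneSetPair, weight_exponent: float = 0.25
) -> pd.DataFrame:
    """Per-sample EMT score in [-1, +1].

    Each signature's enrichment is min-max normalized to [0, 1] across the
    cohort and the score is norm(ES_mesenchymal) - norm(ES_epithelial);
    swapping the two signatures negates every score exactly.
    """
    if expr.shape[1] < 2:
        raise ValueError("cohort normalization needs >=2 samples")
    es_e = np.array([ssgsea_es(expr[s], signatures.epithelial, weight_exponent) for s in expr.columns])
    es_m = np.array([ssgsea_es(expr[s], signatures.mesenchymal, weight_exponent) for s in expr.columns])

    def _minmax(v: np.ndarray) -> np.ndarray:
        span = v.max() - v.min()
        if span == 0:
            return np.full_like(v, 0.5)
        return (v - v.min()) / span

    score = _minmax(es_m) - _minmax(es_e)
    return pd.DataFrame(
        {
            "sample_id": list(expr.columns),
            "es_epithelial": es_e,
            "es_mesenchymal": es_m,
            "emt_score": score,
        }
    )


def gene_emt_association(values: pd.Series, emt: pd.DataFrame) -> tuple[float, float]:
    """Spearman correlation of a gene's expression with the EMT score."""
    scores = emt.set_index("sample_id")["emt_score"]
    common = values.index.intersection(scores.index)
    if len(common) < 10:
        raise ValueError("need >=10 samples with both expression and EMT score")
    v = values.loc[common].to_numpy(float)
    if np.ptp(v) == 0:
        raise ValueError("constant gene; correlation undefined")
    rho, p = stats.spearmanr(v, scores.loc[common].to_numpy(float))
    return float(rho), float(p)
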