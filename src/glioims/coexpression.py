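"""Co-expression module detection and subtype enrichment scoring.

The network follows the weighted co-expression construction used for the
transcriptome analysis: adjacency ``|pearson corr|**beta`` (unsigned, soft
threshold beta = 9 by default), dissimilarity ``1 - adjacency``, average
linkage hierarchical clustering cut at a dissimilarity of 0.8, small clusters
pooled as "not correlated", and modules with near-identical eigengenes
(first principal component of the module's genes) merged.

Module-subtype association is scored by a normalized enrichment score (NES):
genes are ranked by their mean z-scored expression within the subtype's
samples, a weighted Kolmogorov-Smirnov running sum gives the enrichment score
of the module's gene set, and the score is normalised against a gene-set
permutation null (NES = ES / mean |null ES|), with Benjamini-Hochberg
adjustment across module x subtype.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .synth_data import ExpressionStudy

logger = logging.getLogger(__name__)

__all__ = [
    "Module",
    "ModuleSet",
    "NESResult",
    "detect_modules",
    "enrichment_score",
    "module_subtype_nes",
]

NOT_CORRELATED = "not_correlated"


@dataclass
class Module:
    module_id: str
    genes: list[str]
    hub_genes: list[str]

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class ModuleSet:
    modules: list[Module]
    not_correlated: list[str]
    beta: float
    diss_cutoff: float
    eigengenes: pd.DataFrame | None = None   # samples x modules

    def assignment(self) -> pd.Series:
        """Gene -> module id, with pooled genes labelled ``not_correlated``."""
        mapping = {g: m.module_id for m in self.modules for g in m.genes}
        mapping.update({g: NOT_CORRELATED for g in self.not_correlated})
        return pd.Series(mapping, name="module")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for m in self.modules:
            for g in m.genes:
                rows.append({"gene": g, "module": m.module_id,
                             "hub": g in m.hub_genes})
        for g in self.not_correlated:
            rows.append({"gene": g, "module": NOT_CORRELATED, "hub": False})
        return pd.DataFrame(rows)


def _eigengene(z: np.ndarray) -> np.ndarray:
    """First principal component of a genes x samples block (sample scores),
    oriented to correlate positively with the mean expression profile."""
    u, s, vt = np.linalg.svd(z - z.mean(axis=1, keepdims=True),
                             full_matrices=False)
    pc = vt[0]
    if np.corrcoef(pc, z.mean(axis=0))[0, 1] < 0:
        pc = -pc
    return pc


def detect_modules(
    study: ExpressionStudy,
    beta: float = 9.0,
    diss_cutoff: float = 0.8,
    min_size: int = 10,
    merge_threshold: float = 0.9,
    n_hubs: int = 5,
    seed: int = 0,
    top_variance_genes: int | None = None,
) -> ModuleSet:
    """Detect co-expression modules from a genes x samples matrix.

    ``top_variance_genes`` optionally restricts the network to the most
    variable genes before construction (off by default). Constant genes are
    dropped with a warning. Deterministic; ``seed`` is accepted for interface
    symmetry but the procedure has no random step.
    """
    expr = study.expr
    variances = expr.var(axis=1)
    constant = variances <= 1e-24
    if constant.any():
        logger.warning("detect_modules: dropping %d constant genes",
                       int(constant.sum()))
        expr = expr.loc[~constant]
        variances = variances.loc[~constant]
    if top_variance_genes is not None:
        expr = expr.loc[variances.nlargest(top_variance_genes).index]
    genes = list(expr.index)
    if len(genes) < 2 * min_size:
        raise ValueError("need at least 2 x min_size genes")

    corr = np.corrcoef(expr.to_numpy())
    adjacency = np.abs(corr) ** beta
    np.fill_diagonal(adjacency, 1.0)
    dissimilarity = 1.0 - adjacency

    link = average(squareform(dissimilarity, checks=False))
    labels = fcluster(link, t=diss_cutoff, criterion="distance")

    z = ((expr.T - expr.T.mean()) / expr.T.std()).T.to_numpy()
    raw_modules: list[list[int]] = []
    pooled: list[str] = []
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        if idx.size >= min_size:
            raw_modules.append(list(idx))
        else:
            pooled.extend(genes[i] for i in idx)
    # sort by size for stable naming
    raw_modules.sort(key=len, reverse=True)

    # merge modules whose eigengenes correlate above the threshold
    eigengenes = [_eigengene(z[idx]) for idx in raw_modules]
    merged: list[list[int]] = []
    merged_eigs: list[np.ndarray] = []
    for idx, eig in zip(raw_modules, eigengenes):
        target = None
        for j, other in enumerate(merged_eigs):
            if np.corrcoef(eig, other)[0, 1] > merge_threshold:
                target = j
                break
        if target is None:
            merged.append(list(idx))
            merged_eigs.append(eig)
        else:
            merged[target].extend(idx)
            merged_eigs[target] = _eigengene(z[merged[target]])

    modules = []
    eig_table = {}
    for rank, (idx, eig) in enumerate(zip(merged, merged_eigs), start=1):
        module_genes = [genes[i] for i in idx]
        connectivity = adjacency[np.ix_(idx, idx)].sum(axis=1)
        hubs = [module_genes[i]
                for i in np.argsort(connectivity)[::-1][:n_hubs]]
        module_id = f"M{rank}"
        modules.append(Module(module_id, module_genes, hubs))
        eig_table[module_id] = eig
    return ModuleSet(
        modules=modules,
        not_correlated=pooled,
        beta=beta,
        diss_cutoff=diss_cutoff,
        eigengenes=pd.DataFrame(eig_table, index=expr.columns)
        if eig_table else None,
    )


def enrichment_score(
    ranked_metric: pd.Series, gene_set: set[str], weight: float = 1.0
) -> float:
    """Weighted KS running-sum enrichment score of a gene set.

    ``ranked_metric`` is the per-gene ranking statistic (any order; sorted
    descending internally). Hits advance the running sum proportionally to
    ``|metric|**weight``; misses retreat by 1/(N - n_hits). The ES is the
    extreme deviation (keeping its sign).
    """
    metric = ranked_metric.sort_values(ascending=False)
    is_hit = metric.index.isin(gene_set)
    n_miss = len(metric) - int(is_hit.sum())
    if is_hit.sum() == 0 or n_miss == 0:
        raise ValueError("gene set must be a non-trivial subset of the ranking")
    hit_w = np.where(is_hit, np.abs(metric.to_numpy()) ** weight, 0.0)
    total = hit_w.sum()
    if total == 0:
        hit_w = is_hit.astype(float)
        total = hit_w.sum()
    steps = hit_w / total - (~is_hit).astype(float) / n_miss
    running = np.cumsum(steps)
    return float(running[np.argmax(np.abs(running))])


@dataclass
class NESResult:
    nes: pd.DataFrame       # modules x subtypes
    es: pd.DataFrame
    p: pd.DataFrame
    p_adj: pd.DataFrame


def module_subtype_nes(
    moduleset: ModuleSet,
    study: ExpressionStudy,
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
) -> NESResult:
    """NES of every module against every subtype with a permutation null.

    For each subtype, genes are ranked by mean z-scored expression over that
    subtype's samples. The null draws ``n_perm`` size-matched random gene
    sets; NES = ES / mean |null ES| and the two-sided permutation p-value is
    BH-adjusted across the module x subtype grid.
    """
    counts = study.subtypes.value_counts()
    if (counts < 3).any():
        raise ValueError("every subtype needs at least 3 samples")
    expr = study.expr
    z = expr.sub(expr.mean(axis=1), axis=0).div(expr.std(axis=1) + 1e-12,
                                                axis=0)
    genes = np.array(expr.index)
    rng = np.random.default_rng(seed)
    subtypes = sorted(study.subtypes.unique())

    nes = pd.DataFrame(index=[m.module_id for m in moduleset.modules],
                       columns=subtypes, dtype=float)
    es_table = nes.copy()
    p_table = nes.copy()
    for subtype in subtypes:
        cols = study.subtypes.index[study.subtypes == subtype]
        metric = z[cols].mean(axis=1)
        for module in moduleset.modules:
            if len(module) > len(genes) // 2:
                warnings.warn(
                    f"module {module.module_id} covers more than half of all "
                    f"genes; NES may be unstable", stacklevel=2,
                )
            es = enrichment_score(metric, set(module.genes), weight=weight)
            null = np.empty(n_perm)
            for b in range(n_perm):
                random_set = set(
                    rng.choice(genes, size=len(module), replace=False)
                )
                null[b] = enrichment_score(metric, random_set, weight=weight)
            scale = np.abs(null).mean()
            nes.loc[module.module_id, subtype] = es / scale
            es_table.loc[module.module_id, subtype] = es
            p_table.loc[module.module_id, subtype] = (
                (1 + np.sum(np.abs(null) >= abs(es))) / (1 + n_perm)
            )

    flat = p_table.to_numpy(float).ravel()
    adj = multipletests(flat, method="fdr_bh")[1].reshape(p_table.shape)
    return NESResult(
        nes=nes.astype(float),
        es=es_table.astype(float),
        p=p_table.astype(float),
        p_adj=pd.DataFrame(adj, index=p_table.index, columns=p_table.columns),
    )
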