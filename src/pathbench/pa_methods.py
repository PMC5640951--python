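"""Pathway-analysis methods: ORA, GSA, GSEA and AFC with permutation nulls.

Six method variants are supported, following the common benchmarking grid:

* **ORA** — over-representation analysis: a hypergeometric test on the overlap
  between differentially expressed (DE) genes and each pathway, run once per
  direction (DE genes split by the sign of the t-statistic).
* **GSA** — maxmean statistic with Efron–Tibshirani restandardization, which
  combines gene-label and sample-label permutation into one null.
* **GSEA / GSEAs** — weighted Kolmogorov–Smirnov running-sum enrichment score,
  with a gene-label (GSEA) or sample-label (GSEAs) permutation null.
* **AFC / AFCs** — aggregate fold change: the pathway score is the mean of the
  per-gene mean log2 fold changes, again with either permutation null.

Every method reports, per pathway, a signed score and one-sided permutation
p-values ``p_up`` (probability a null score is >= the observed score) and
``p_down`` (<=), and ranks the top-K up- and down-regulated pathways.

Sample-label nulls with few samples are enumerated exactly: when the number of
distinct label assignments (complementary assignments identified for equal
cohort sizes, e.g. 10 for 3 vs 3) is at most the permutation budget, all of
them are used and p-values are exact counts; otherwise assignments are sampled
and the add-one estimator (b+1)/(B+1) keeps p-values in (0, 1].
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._rng import derive_rng
from .expression import ExpressionDataset, count_distinct_label_assignments
from .genesets import GeneSetCollection, restrict_to_measured

__all__ = [
    "GeneStats",
    "MethodConfig",
    "PathwayRanking",
    "METHOD_VARIANTS",
    "method_config",
    "compute_gene_stats",
    "afc_score",
    "gsa_maxmean",
    "gsea_enrichment_score",
    "ora_pvalues",
    "ora_rank",
    "permutation_pvalues",
    "rank_top_k",
    "rank_pathways",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Per-gene statistics


@dataclass(frozen=True)
class GeneStats:
    """Per-gene two-cohort statistics for one dataset, aligned to gene order.

    ``fold_change`` is treatment mean minus control mean of the (already
    log2-scale) expression values; ``t`` and ``p`` are the two-sample
    Student t-statistic and its two-sided p-value.
    """

    gene_ids: tuple[str, ...]
    t: np.ndarray
    p: np.ndarray
    fold_change: np.ndarray


def _t_from_moments(diff, var1, var2, n1, n2, welch=False):
    if welch:
        se2 = var1 / n1 + var2 / n2
        with np.errstate(divide="ignore", invalid="ignore"):
            df = se2**2 / (
                (var1 / n1) ** 2 / (n1 - 1) + (var2 / n2) ** 2 / (n2 - 1)
            )
        df = np.where(np.isfinite(df), df, n1 + n2 - 2)
    else:
        sp2 = ((n1 - 1) * var1 + (n2 - 1) * var2) / (n1 + n2 - 2)
        se2 = sp2 * (1.0 / n1 + 1.0 / n2)
        df = np.full_like(np.asarray(se2, dtype=float), n1 + n2 - 2)
    se = np.sqrt(se2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    # zero within-group variance: t -> +/-inf with p ~ 0 (or 0/1 if no change)
    degenerate = se == 0
    t = np.where(degenerate & (diff > 0), np.inf, t)
    t = np.where(degenerate & (diff < 0), -np.inf, t)
    t = np.where(degenerate & (diff == 0), 0.0, t)
    p = np.where(np.isinf(t), 0.0, 2.0 * sps.t.sf(np.abs(np.where(np.isinf(t), 0, t)), df))
    p = np.where(degenerate & (diff == 0), 1.0, p)
    return t, p


def compute_gene_stats(D: ExpressionDataset, welch: bool = False) -> GeneStats:
    """Student's pooled-variance t (Welch by flag) and mean log2 fold change."""
    mask = D.treatment_mask
    n1, n2 = int(mask.sum()), int((~mask).sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("each cohort needs >=2 samples for gene statistics")
    X1, X2 = D.values[:, mask], D.values[:, ~mask]
    m1, m2 = X1.mean(axis=1), X2.mean(axis=1)
    v1, v2 = X1.var(axis=1, ddof=1), X2.var(axis=1, ddof=1)
    diff = m1 - m2
    t, p = _t_from_moments(diff, v1, v2, n1, n2, welch=welch)
    if np.isinf(t).any():
        logger.warning(
            "%d gene(s) with zero within-group variance; t set to +/-inf, p=0",
            int(np.isinf(t).sum()),
        )
    return GeneStats(gene_ids=D.gene_ids, t=t, p=p, fold_change=diff)


def _stats_for_masks(X: np.ndarray, masks: np.ndarray, welch: bool = False):
    """t-statistics and fold changes for many label assignments at once.

    ``masks`` is samples × B boolean (True = treatment); cohort sizes are
    constant across columns. Returns (t, fc), each genes × B.
    """
    M = masks.astype(float)
    n1 = float(masks[:, 0].sum())
    n2 = masks.shape[0] - n1
    s1 = X @ M
    sq1 = (X**2) @ M
    s_tot = X.sum(axis=1, keepdims=True)
    sq_tot = (X**2).sum(axis=1, keepdims=True)
    m1 = s1 / n1
    m2 = (s_tot - s1) / n2
    v1 = (sq1 - n1 * m1**2) / (n1 - 1)
    v2 = ((sq_tot - sq1) - n2 * m2**2) / (n2 - 1)
    v1 = np.maximum(v1, 0.0)  # guard tiny negative from cancellation
    v2 = np.maximum(v2, 0.0)
    diff = m1 - m2
    t, _ = _t_from_moments(diff, v1, v2, n1, n2, welch=welch)
    return t, diff


# ---------------------------------------------------------------------------
# Pathway scoring statistics


def afc_score(stats: GeneStats, genes) -> float:
    """Aggregate fold change: mean of member genes' mean log2 fold changes."""
    idx = _gene_indices(stats.gene_ids, genes)
    return float(stats.fold_change[idx].mean())


def gsa_maxmean(stats: GeneStats, genes) -> float:
    """Maxmean statistic on per-gene t-statistics.

    s+ is the mean positive part, s- the mean negative part (both averaged
    over all member genes); the signed score keeps whichever is larger.
    """
    idx = _gene_indices(stats.gene_ids, genes)
    z = stats.t[idx]
    s_pos = np.maximum(z, 0.0).mean()
    s_neg = np.maximum(-z, 0.0).mean()
    return float(s_pos) if s_pos > s_neg else float(-s_neg)


def _gene_indices(gene_ids, genes) -> np.ndarray:
    pos = {g: i for i, g in enumerate(gene_ids)}
    idx = np.asarray([pos[g] for g in genes if g in pos], dtype=int)
    if idx.size == 0:
        raise ValueError("gene set has no measured genes")
    return idx


def gsea_enrichment_score(
    ranked_genes, weights, member_genes, p: float = 1.0
) -> float:
    """Weighted Kolmogorov–Smirnov enrichment score.

    ``ranked_genes`` is the full measured gene list ordered by the correlation
    statistic (most up-regulated first) and ``weights`` the per-gene statistic
    magnitudes in the same order.  The running sum increases by
    ``|w|^p / sum_hits |w|^p`` at member genes and decreases by
    ``1/(N - N_hits)`` at non-members; the ES is the running-sum value of
    maximal absolute deviation from zero (signed; ties resolve positive).
    """
    ranked_genes = list(ranked_genes)
    members = set(member_genes)
    hits = np.flatnonzero([g in members for g in ranked_genes])
    if hits.size == 0:
        raise ValueError("gene set has no genes in the ranked list")
    if hits.size == len(ranked_genes):
        raise ValueError("gene set covers every measured gene; ES undefined")
    w = np.abs(np.asarray(weights, dtype=float)) ** p
    es = _es_batch(hits[None, :], w[hits][None, :], len(ranked_genes))
    return float(es[0])


def _es_batch(hits: np.ndarray, hit_weights: np.ndarray, n_genes: int) -> np.ndarray:
    """Enrichment scores for batches of hit-position vectors.

    ``hits`` (B × m) are 0-based positions in the ranked list, ascending per
    row; ``hit_weights`` the corresponding |statistic|^p values.  The running
    sum is piecewise linear between hits, so its extrema occur just after a
    hit (maxima candidates) or just before one (minima candidates).
    """
    B, m = hits.shape
    n_miss = n_genes - m
    if n_miss <= 0:
        raise ValueError("gene set covers every measured gene; ES undefined")
    W = hit_weights.sum(axis=1, keepdims=True)
    zero_w = W[:, 0] == 0
    if zero_w.any():  # all member stats exactly zero: fall back to equal weights
        hit_weights = np.where(zero_w[:, None], 1.0, hit_weights)
        W = hit_weights.sum(axis=1, keepdims=True)
    cw = np.cumsum(hit_weights, axis=1) / W
    j = np.arange(1, m + 1)
    dev_hi = cw - (hits + 1 - j) / n_miss
    dev_lo = (cw - hit_weights / W) - (hits - (j - 1)) / n_miss
    es_pos = dev_hi.max(axis=1)
    es_neg = np.minimum(dev_lo.min(axis=1), 0.0)
    # |deviation| ties (up to float noise) resolve to the positive side
    return np.where(es_pos >= -es_neg - 1e-9, es_pos, es_neg)


# ---------------------------------------------------------------------------
# Configuration and ranking containers

METHOD_VARIANTS = ("ora", "gsa", "gsea", "gseas", "afc", "afcs")

_VALID_MODES = {
    "ora": ("none",),
    "gsa": ("restandardization",),
    "gsea": ("gene_label", "sample_label"),
    "afc": ("gene_label", "sample_label"),
}


@dataclass(frozen=True)
class MethodConfig:
    """Full parameterization of one PA method variant.

    ``de_alpha`` is ORA's DE cutoff on the two-sided t-test p-value;
    ``gsea_weight`` the exponent of the weighted KS statistic; ``rank_by``
    the gene-ordering statistic for GSEA ("t" or "fold_change").
    """

    method: str
    permutation_mode: str
    n_permutations: int = 1000
    de_alpha: float = 0.05
    gsea_weight: float = 1.0
    rank_by: str = "t"
    welch: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in _VALID_MODES:
            raise ValueError(f"unknown method {self.method!r}")
        if self.permutation_mode not in _VALID_MODES[self.method]:
            raise ValueError(
                f"method {self.method!r} does not support permutation mode "
                f"{self.permutation_mode!r}"
            )
        if self.permutation_mode != "none" and self.n_permutations < 1:
            raise ValueError("n_permutations must be >=1 for permutation nulls")
        if not 0.0 < self.de_alpha < 1.0:
            raise ValueError("de_alpha must lie in (0, 1)")
        if self.rank_by not in ("t", "fold_change"):
            raise ValueError(f"unknown rank_by {self.rank_by!r}")

    @property
    def uses_sample_permutation(self) -> bool:
        return self.permutation_mode in ("sample_label", "restandardization")


def method_config(name: str, **overrides) -> MethodConfig:
    """Build the config for a named variant: ora, gsa, gsea, gseas, afc, afcs."""
    name = name.lower()
    table = {
        "ora": ("ora", "none"),
        "gsa": ("gsa", "restandardization"),
        "gsea": ("gsea", "gene_label"),
        "gseas": ("gsea", "sample_label"),
        "afc": ("afc", "gene_label"),
        "afcs": ("afc", "sample_label"),
    }
    if name not in table:
        raise ValueError(f"unknown method variant {name!r}; expected one of {METHOD_VARIANTS}")
    method, mode = table[name]
    return MethodConfig(method=method, permutation_mode=mode, **overrides)


@dataclass(frozen=True)
class PathwayRanking:
    """Ordered top-K up- and down-regulated pathway id lists."""

    k: int
    up: tuple[str, ...]
    down: tuple[str, ...]

    def __post_init__(self) -> None:
        for name, ids in (("up", self.up), ("down", self.down)):
            if len(set(ids)) != len(ids):
                raise ValueError(f"duplicate pathway ids in {name} list")

    def direction(self, which: str) -> tuple[str, ...]:
        if which not in ("up", "down"):
            raise ValueError(f"direction must be 'up' or 'down', got {which!r}")
        return self.up if which == "up" else self.down


# ---------------------------------------------------------------------------
# Restriction helpers


def _restricted_membership(D: ExpressionDataset, coll: GeneSetCollection):
    """Collection restricted to measured genes + boolean membership matrix."""
    measured = set(D.gene_ids)
    coll_r = restrict_to_measured(coll, measured)
    gene_pos = {g: i for i, g in enumerate(D.gene_ids)}
    n_sets = len(coll_r)
    M = np.zeros((n_sets, D.n_genes), dtype=bool)
    for s, gs in enumerate(coll_r):
        M[s, [gene_pos[g] for g in gs.genes]] = True
    return coll_r, M


# ---------------------------------------------------------------------------
# ORA


def ora_pvalues(
    D: ExpressionDataset, coll: GeneSetCollection, cfg: MethodConfig
) -> pd.DataFrame:
    """Directional over-representation p-values by the hypergeometric test.

    DE genes (t-test p < ``de_alpha``) are split by the sign of t; each
    direction gets an upper-tail hypergeometric test of the overlap between
    the pathway and that direction's DE genes.  The universe is the measured
    genes that appear in the collection.
    """
    coll_r, M = _restricted_membership(D, coll)
    stats = compute_gene_stats(D, welch=cfg.welch)
    in_universe = M.any(axis=0)
    n_universe = int(in_universe.sum())
    de_up = (stats.p < cfg.de_alpha) & (stats.t > 0) & in_universe
    de_down = (stats.p < cfg.de_alpha) & (stats.t < 0) & in_universe
    n_up, n_down = int(de_up.sum()), int(de_down.sum())
    if n_up == 0 or n_down == 0:
        logger.warning(
            "ORA: no DE genes in %s direction(s); that tail is uniformly p=1",
            "both" if n_up == n_down == 0 else ("up" if n_up == 0 else "down"),
        )
    sizes = M.sum(axis=1)
    k_up = M.astype(int) @ de_up.astype(int)
    k_down = M.astype(int) @ de_down.astype(int)
    # upper tail P(X >= k) for X ~ Hypergeom(universe, set size, #DE drawn)
    p_up = sps.hypergeom.sf(k_up - 1, n_universe, sizes, n_up)
    p_down = sps.hypergeom.sf(k_down - 1, n_universe, sizes, n_down)
    return pd.DataFrame(
        {
            "pathway_id": coll_r.ids,
            "size": sizes,
            "score": k_up.astype(float) - k_down.astype(float),
            "p_up": p_up,
            "p_down": p_down,
        }
    )


def ora_rank(
    D: ExpressionDataset, coll: GeneSetCollection, cfg: MethodConfig, K: int
) -> PathwayRanking:
    return rank_top_k(ora_pvalues(D, coll, cfg), K, signed=False)


# ---------------------------------------------------------------------------
# Permutation nulls for AFC / GSEA / GSA


def _afc_scores_matrix(M: np.ndarray, fc: np.ndarray) -> np.ndarray:
    """AFC scores for each set; fc may be (G,) or (G, B)."""
    sizes = M.sum(axis=1, keepdims=True)
    return (M.astype(float) @ np.atleast_2d(fc.T).T) / sizes


def _maxmean_scores_matrix(M: np.ndarray, z: np.ndarray) -> np.ndarray:
    z2 = z if z.ndim == 2 else z[:, None]
    sizes = M.sum(axis=1, keepdims=True)
    Mf = M.astype(float)
    s_pos = (Mf @ np.maximum(z2, 0.0)) / sizes
    s_neg = (Mf @ np.maximum(-z2, 0.0)) / sizes
    out = np.where(s_pos > s_neg, s_pos, -s_neg)
    return out if z.ndim == 2 else out[:, 0]


def _sanitize_stat(stat: np.ndarray) -> np.ndarray:
    """Replace infinite statistics (zero-variance genes) by the largest finite
    magnitude so rankings stay usable and KS weights stay finite."""
    if not np.isinf(stat).any():
        return stat
    finite = np.abs(stat[np.isfinite(stat)])
    cap = finite.max() if finite.size else 1.0
    return np.clip(stat, -cap, cap)


def _gsea_scores_for_stat(M: np.ndarray, stat: np.ndarray, p: float) -> np.ndarray:
    """Observed-ordering GSEA ES for all sets given one gene statistic vector."""
    stat = _sanitize_stat(np.asarray(stat, dtype=float))
    order = np.argsort(-stat, kind="stable")
    pos = np.empty_like(order)
    pos[order] = np.arange(order.size)
    w = np.abs(stat) ** p
    out = np.empty(M.shape[0])
    for s in range(M.shape[0]):
        gidx = np.flatnonzero(M[s])
        hp = pos[gidx]
        srt = np.argsort(hp)
        out[s] = _es_batch(hp[srt][None, :], w[gidx][srt][None, :], stat.size)[0]
    return out


def _gsea_scores_sample_null(
    M: np.ndarray, t_null: np.ndarray, p: float
) -> np.ndarray:
    """GSEA ES per set for each column of t_null (genes × B)."""
    B = t_null.shape[1]
    out = np.empty((M.shape[0], B))
    for b in range(B):
        out[:, b] = _gsea_scores_for_stat(M, t_null[:, b], p)
    return out


def _gsea_scores_gene_null(
    M: np.ndarray, stat: np.ndarray, p: float, B: int, rng: np.random.Generator
) -> np.ndarray:
    """Gene-label null: member positions become random subsets of the ranked
    list, which is equivalent to permuting the gene labels."""
    stat = _sanitize_stat(np.asarray(stat, dtype=float))
    order = np.argsort(-stat, kind="stable")
    w_sorted = np.abs(stat[order]) ** p
    G = stat.size
    out = np.empty((M.shape[0], B))
    # one shared pool of permutations keeps this O(B G log G) overall
    perms = np.argsort(rng.random((B, G)), axis=1)
    for s in range(M.shape[0]):
        m = int(M[s].sum())
        hits = np.sort(perms[:, :m], axis=1)
        out[s] = _es_batch(hits, w_sorted[hits], G)
    return out


def _enumerate_assignments(n_samples: int, treat_idx: np.ndarray) -> np.ndarray:
    """All distinct treatment/control assignments as a samples × B bool matrix.

    For equal cohort sizes an assignment and its complement give the same
    split; the representative containing the first observed treatment sample
    is kept, so the observed labeling itself is always among the columns.
    """
    n1 = treat_idx.size
    anchor = treat_idx[0]
    cols = []
    for combo in itertools.combinations(range(n_samples), n1):
        if 2 * n1 == n_samples and anchor not in combo:
            continue  # complement of a kept assignment
        mask = np.zeros(n_samples, dtype=bool)
        mask[list(combo)] = True
        cols.append(mask)
    return np.stack(cols, axis=1)


def _sample_assignments(
    n_samples: int, n1: int, B: int, rng: np.random.Generator
) -> np.ndarray:
    masks = np.zeros((n_samples, B), dtype=bool)
    for b in range(B):
        masks[rng.choice(n_samples, size=n1, replace=False), b] = True
    return masks


def _null_scores_sample_label(
    D: ExpressionDataset,
    M: np.ndarray,
    scorer: str,
    cfg: MethodConfig,
    rng: np.random.Generator,
):
    """Null scores under cohort-label reassignment. Returns (scores S×B, exact).

    ``exact`` is True when all distinct assignments were enumerated (the
    observed labeling included), in which case p-values are exact counts.
    """
    n1, n2 = D.n_treatment, D.n_control
    if n1 < 2 or n2 < 2:
        raise ValueError("sample-label permutation needs >=2 samples per cohort")
    n_distinct = count_distinct_label_assignments(n1, n2)
    if n_distinct <= cfg.n_permutations:
        masks = _enumerate_assignments(D.n_samples, np.flatnonzero(D.treatment_mask))
        exact = True
    else:
        masks = _sample_assignments(D.n_samples, n1, cfg.n_permutations, rng)
        exact = False
    # score the observed labeling through the identical numerical path, so
    # the identity assignment inside an enumerated null compares as a tie
    masks = np.column_stack([D.treatment_mask, masks])
    t_null, fc_null = _stats_for_masks(D.values, masks, welch=cfg.welch)
    if scorer == "afc":
        null = _afc_scores_matrix(M, fc_null)
    elif scorer == "gsa":
        null = _maxmean_scores_matrix(M, t_null)
    elif scorer == "gsea":
        null = _gsea_scores_sample_null(M, t_null, cfg.gsea_weight)
    else:
        raise ValueError(f"unknown scorer {scorer!r}")
    return null[:, 1:], exact, null[:, 0]


def permutation_pvalues(
    D: ExpressionDataset,
    coll: GeneSetCollection,
    scorer: str,
    cfg: MethodConfig,
) -> pd.DataFrame:
    """Pathway score table with permutation p-values for AFC, GSEA or GSA.

    gene_label mode permutes the assignment of per-gene statistics to gene
    identities; sample_label mode reassigns cohort labels (preserving cohort
    sizes) and recomputes the gene statistics; restandardization (GSA)
    combines both axes following Efron & Tibshirani.  ``p_up`` is the
    probability that a null score is >= the observed score; ``p_down`` uses
    <=.  Exact enumeration replaces sampling when feasible (see module notes).
    """
    if scorer not in ("afc", "gsa", "gsea"):
        raise ValueError(f"unknown scorer {scorer!r}")
    coll_r, M = _restricted_membership(D, coll)
    if len(coll_r) == 0:
        raise ValueError("no gene set has measured genes")
    stats = compute_gene_stats(D, welch=cfg.welch)
    rng = derive_rng(cfg.seed, "perm", scorer, cfg.permutation_mode)

    if scorer == "afc":
        gene_stat = stats.fold_change
        observed = _afc_scores_matrix(M, gene_stat)[:, 0]
    else:
        gene_stat = (
            stats.t if not (scorer == "gsea" and cfg.rank_by == "fold_change")
            else stats.fold_change
        )
        if scorer == "gsa":
            observed = _maxmean_scores_matrix(M, gene_stat)
        else:
            observed = _gsea_scores_for_stat(M, gene_stat, cfg.gsea_weight)

    B = cfg.n_permutations
    obs_cmp = observed
    if cfg.permutation_mode == "gene_label":
        if scorer == "gsea":
            null = _gsea_scores_gene_null(M, gene_stat, cfg.gsea_weight, B, rng)
        else:
            perm_stats = np.stack(
                [rng.permutation(gene_stat) for _ in range(B)], axis=1
            )
            null = (
                _afc_scores_matrix(M, perm_stats)
                if scorer == "afc"
                else _maxmean_scores_matrix(M, perm_stats)
            )
        exact = False
    elif cfg.permutation_mode == "sample_label":
        null, exact, obs_cmp = _null_scores_sample_label(D, M, scorer, cfg, rng)
    elif cfg.permutation_mode == "restandardization":
        perm_stats = np.stack([rng.permutation(gene_stat) for _ in range(B)], axis=1)
        gene_null = _maxmean_scores_matrix(M, perm_stats)
        mu_g = gene_null.mean(axis=1)
        sd_g = gene_null.std(axis=1, ddof=1)
        samp_null, _, _ = _null_scores_sample_label(D, M, scorer, cfg, rng)
        mu_s = samp_null.mean(axis=1, keepdims=True)
        sd_s = samp_null.std(axis=1, ddof=1, keepdims=True)
        safe_sd = np.where(sd_s > 0, sd_s, 1.0)
        null = mu_g[:, None] + sd_g[:, None] * (samp_null - mu_s) / safe_sd
        exact = False  # restandardized values are not an exact test
    else:
        raise ValueError(f"permutation mode {cfg.permutation_mode!r} needs a null")

    b_eff = null.shape[1]
    ge = (null >= obs_cmp[:, None]).sum(axis=1)
    le = (null <= obs_cmp[:, None]).sum(axis=1)
    if exact:
        p_up = ge / b_eff
        p_down = le / b_eff
    else:
        p_up = (ge + 1.0) / (b_eff + 1.0)
        p_down = (le + 1.0) / (b_eff + 1.0)
    return pd.DataFrame(
        {
            "pathway_id": coll_r.ids,
            "size": M.sum(axis=1),
            "score": observed,
            "p_up": p_up,
            "p_down": p_down,
        }
    )


# ---------------------------------------------------------------------------
# Top-K ranking


def rank_top_k(table: pd.DataFrame, K: int, signed: bool = True) -> PathwayRanking:
    """Rank pathways into top-K up and down lists.

    Sort key: ascending p, then descending |score|, then pathway id.  For
    signed-score methods a pathway is only eligible for the list matching the
    sign of its score (score exactly zero joins neither).
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > len(table):
        logger.warning("K=%d exceeds %d pathways; returning all", K, len(table))

    def _top(direction: str) -> tuple[str, ...]:
        df = table
        if signed:
            df = df[df["score"] > 0] if direction == "up" else df[df["score"] < 0]
        pcol = "p_up" if direction == "up" else "p_down"
        df = df.assign(_absscore=df["score"].abs()).sort_values(
            [pcol, "_absscore", "pathway_id"], ascending=[True, False, True]
        )
        return tuple(df["pathway_id"].head(K))

    return PathwayRanking(k=K, up=_top("up"), down=_top("down"))


def rank_pathways(
    D: ExpressionDataset,
    coll: GeneSetCollection,
    cfg: MethodConfig,
    K: int,
    seed: int | None = None,
) -> PathwayRanking:
    """Run one PA method variant end to end and return its top-K ranking.

    ``seed`` overrides ``cfg.seed`` (used by the resampling experiments to
    derive per-replicate permutation streams).
    """
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    if cfg.method == "ora":
        return ora_rank(D, coll, cfg, K)
    scorer = cfg.method  # afc / gsa / gsea
    table = permutation_pvalues(D, coll, scorer, cfg)
    return rank_top_k(table, K, signed=True)
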