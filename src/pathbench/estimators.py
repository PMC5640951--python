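"""Scikit-learn-style estimators for the pathway-analysis methods.

Each ranker follows the estimator contract: constructor parameters are stored
verbatim, ``fit(X, y)`` validates inputs and computes fitted attributes with a
trailing underscore, and ``get_params``/``set_params`` make the rankers usable
with sklearn model-selection utilities.

``X`` is samples × genes (a DataFrame whose columns are gene symbols, or an
array plus ``gene_ids``); ``y`` assigns each sample to ``treatment`` /
``control`` (strings, or binary with 1 = treatment).  After fitting:

``gene_stats_``
    per-gene t-statistics, p-values and mean log2 fold changes;
``score_table_``
    per-pathway signed score with one-sided permutation p-values;
``ranking_``
    the top-K up- and down-regulated pathway id lists.

Example
-------
>>> ranker = AFCRanker(gene_sets=coll, k=20, n_permutations=1000)
>>> ranker.fit(X, y).ranking_.up[:3]
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .expression import CONTROL, TREATMENT, ExpressionDataset
from .genesets import GeneSetCollection
from .pa_methods import (
    MethodConfig,
    PathwayRanking,
    compute_gene_stats,
    ora_pvalues,
    permutation_pvalues,
    rank_top_k,
)

__all__ = [
    "BasePathwayRanker",
    "ORARanker",
    "GSARanker",
    "GSEARanker",
    "AFCRanker",
    "make_ranker",
]


def _dataset_from_xy(X, y, gene_ids=None) -> ExpressionDataset:
    if isinstance(X, ExpressionDataset):
        return X
    if isinstance(X, pd.DataFrame):
        gene_ids = [str(c) for c in X.columns]
        sample_ids = [str(i) for i in X.index]
        values = X.to_numpy(dtype=float).T
    else:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be a 2-D samples x genes matrix")
        if gene_ids is None:
            raise ValueError("array input requires gene_ids")
        if len(gene_ids) != X.shape[1]:
            raise ValueError("gene_ids length must match X's column count")
        sample_ids = [f"sample{i}" for i in range(X.shape[0])]
        values = X.T
    y = np.asarray(y)
    if y.shape[0] != values.shape[1]:
        raise ValueError("y length must match the number of samples")
    labels = set(np.unique(y).tolist())
    if labels <= {0, 1} or labels <= {False, True}:
        cohort = tuple(TREATMENT if v else CONTROL for v in y)
    elif labels <= {TREATMENT, CONTROL}:
        cohort = tuple(str(v) for v in y)
    else:
        raise ValueError(
            f"y must be binary (1 = treatment) or use labels "
            f"{{{TREATMENT!r}, {CONTROL!r}}}, got {sorted(map(str, labels))}"
        )
    return ExpressionDataset(
        gene_ids=tuple(str(g) for g in gene_ids),
        sample_ids=tuple(sample_ids),
        values=values,
        cohort=cohort,
    )


class BasePathwayRanker(BaseEstimator):
    """Shared fit logic; subclasses define the method variant."""

    variant: str = ""  # overridden

    def __init__(self, gene_sets=None, k=20, random_state=0):
        self.gene_sets = gene_sets
        self.k = k
        self.random_state = random_state

    # -- config assembly -------------------------------------------------
    def _config(self, seed: int | None = None) -> MethodConfig:
        raise NotImplementedError

    @property
    def permutation_mode(self) -> str:
        return self._config().permutation_mode

    def _collection(self) -> GeneSetCollection:
        if self.gene_sets is None:
            raise ValueError("gene_sets must be provided before fitting")
        return self.gene_sets

    # -- sklearn surface --------------------------------------------------
    def fit(self, X, y, gene_ids=None):
        """Score all pathways and rank the top-K per direction."""
        D = _dataset_from_xy(X, y, gene_ids=gene_ids)
        cfg = self._config()
        self.gene_stats_ = compute_gene_stats(D, welch=cfg.welch)
        self.score_table_ = self._score_table(D, cfg)
        self.ranking_ = rank_top_k(
            self.score_table_, self.k, signed=cfg.method != "ora"
        )
        self.n_features_in_ = D.n_genes
        return self

    def _score_table(self, D: ExpressionDataset, cfg: MethodConfig) -> pd.DataFrame:
        if cfg.method == "ora":
            return ora_pvalues(D, self._collection(), cfg)
        return permutation_pvalues(D, self._collection(), cfg.method, cfg)

    def top_pathways(self, direction: str = "up") -> tuple[str, ...]:
        if not hasattr(self, "ranking_"):
            raise AttributeError("call fit before top_pathways")
        return self.ranking_.direction(direction)

    # -- domain-level entry used by the resampling experiments ------------
    def rank_dataset(
        self, D: ExpressionDataset, K: int | None = None, seed: int | None = None
    ) -> PathwayRanking:
        cfg = self._config(seed=seed)
        k = self.k if K is None else K
        table = self._score_table(D, cfg)
        return rank_top_k(table, k, signed=cfg.method != "ora")


class ORARanker(BasePathwayRanker):
    """Over-representation analysis: hypergeometric test on DE-gene overlap."""

    variant = "ora"

    def __init__(self, gene_sets=None, k=20, de_alpha=0.05, welch=False,
                 random_state=0):
        super().__init__(gene_sets=gene_sets, k=k, random_state=random_state)
        self.de_alpha = de_alpha
        self.welch = welch

    def _config(self, seed=None) -> MethodConfig:
        return MethodConfig(
            method="ora",
            permutation_mode="none",
            de_alpha=self.de_alpha,
            welch=self.welch,
            seed=self.random_state if seed is None else seed,
        )


class GSARanker(BasePathwayRanker):
    """Maxmean statistic with restandardized permutation null."""

    variant = "gsa"

    def __init__(self, gene_sets=None, k=20, n_permutations=1000, welch=False,
                 random_state=0):
        super().__init__(gene_sets=gene_sets, k=k, random_state=random_state)
        self.n_permutations = n_permutations
        self.welch = welch

    def _config(self, seed=None) -> MethodConfig:
        return MethodConfig(
            method="gsa",
            permutation_mode="restandardization",
            n_permutations=self.n_permutations,
            welch=self.welch,
            seed=self.random_state if seed is None else seed,
        )


class GSEARanker(BasePathwayRanker):
    """Weighted KS enrichment score; gene- or sample-label permutation null."""

    variant = "gsea"

    def __init__(self, gene_sets=None, k=20, n_permutations=1000,
                 permutation="gene_label", gsea_weight=1.0, rank_by="t",
                 welch=False, random_state=0):
        super().__init__(gene_sets=gene_sets, k=k, random_state=random_state)
        self.n_permutations = n_permutations
        self.permutation = permutation
        self.gsea_weight = gsea_weight
        self.rank_by = rank_by
        self.welch = welch

    @property
    def variant_name(self) -> str:
        return "gseas" if self.permutation == "sample_label" else "gsea"

    def _config(self, seed=None) -> MethodConfig:
        return MethodConfig(
            method="gsea",
            permutation_mode=self.permutation,
            n_permutations=self.n_permutations,
            gsea_weight=self.gsea_weight,
            rank_by=self.rank_by,
            welch=self.welch,
            seed=self.random_state if seed is None else seed,
        )


class AFCRanker(BasePathwayRanker):
    """Aggregate fold change; gene- or sample-label permutation null."""

    variant = "afc"

    def __init__(self, gene_sets=None, k=20, n_permutations=1000,
                 permutation="gene_label", welch=False, random_state=0):
        super().__init__(gene_sets=gene_sets, k=k, random_state=random_state)
        self.n_permutations = n_permutations
        self.permutation = permutation
        self.welch = welch

    @property
    def variant_name(self) -> str:
        return "afcs" if self.permutation == "sample_label" else "afc"

    def _config(self, seed=None) -> MethodConfig:
        return MethodConfig(
            method="afc",
            permutation_mode=self.permutation,
            n_permutations=self.n_permutations,
            welch=self.welch,
            seed=self.random_state if seed is None else seed,
        )


def make_ranker(name: str, gene_sets=None, **kwargs) -> BasePathwayRanker:
    """Build the ranker for a named variant: ora, gsa, gsea, gseas, afc, afcs."""
    name = name.lower()
    if name == "ora":
        return ORARanker(gene_sets=gene_sets, **kwargs)
    if name == "gsa":
        return GSARanker(gene_sets=gene_sets, **kwargs)
    if name in ("gsea", "gseas"):
        mode = "sample_label" if name == "gseas" else "gene_label"
        return GSEARanker(gene_sets=gene_sets, permutation=mode, **kwargs)
    if name in ("afc", "afcs"):
        mode = "sample_label" if name == "afcs" else "gene_label"
        return AFCRanker(gene_sets=gene_sets, permutation=mode, **kwargs)
    raise ValueError(f"unknown method variant {name!r}")
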