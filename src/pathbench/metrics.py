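"""Gold-standard-free evaluation metrics: recall and discrimination.

The strategy evaluates a pathway-analysis method without knowing the truly
perturbed pathways, by controlled resampling:

* **recall** ``r(A, a) = |A ∩ a| / |A|`` measures *consistency*: how much of
  the top-K pathway list ``A`` from a full dataset ``D`` is recovered in the
  list ``a`` from a small sub-dataset ``d`` resampled from ``D``.
* **discrimination** ``s`` measures *specificity*: given two datasets from
  different conditions with full-data lists ``A`` and ``A'`` and M sub-dataset
  lists each, a sub-dataset is correctly associated when its recall against
  its own parent strictly exceeds its recall against the other dataset; ``s``
  is the fraction of correct associations (ties count as incorrect, so two
  identical parents give s = 0).

Both metrics are computed separately for up- and down-regulated lists.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np

from ._rng import derive_seed
from .expression import ExpressionDataset, SubsampleSpec, subsample
from .genesets import GeneSetCollection
from .pa_methods import MethodConfig, PathwayRanking, rank_pathways

__all__ = [
    "RecallResult",
    "DiscriminationResult",
    "recall",
    "discrimination",
    "generalized_discrimination",
    "run_recall_experiment",
    "run_discrimination_experiment",
    "cross_dataset_overlap",
    "variant_name",
]

logger = logging.getLogger(__name__)

DIRECTIONS = ("up", "down")


@dataclass(frozen=True)
class RecallResult:
    """Recall values for one (method, direction, K, sub-dataset size) cell."""

    method: str
    direction: str
    k: int
    n: int
    recalls: tuple[float, ...]
    dataset_id: str = ""

    @property
    def mean(self) -> float:
        return sum(self.recalls) / len(self.recalls) if self.recalls else float("nan")


@dataclass(frozen=True)
class DiscriminationResult:
    """Correct-association counts and the discrimination fraction s."""

    correct: int
    total: int
    method: str = ""
    direction: str = ""
    k: int = 0
    n: int = 0
    dataset_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not 0 <= self.correct <= self.total:
            raise ValueError("require 0 <= correct <= total")

    @property
    def s(self) -> float:
        return self.correct / self.total


def recall(A: Sequence[str], a: Sequence[str]) -> float:
    """Fraction of the full-dataset list A recovered in the sub-dataset list a."""
    A_set = set(A)
    if not A_set:
        raise ValueError("recall is undefined for an empty reference list A")
    return len(A_set & set(a)) / len(A_set)


def discrimination(
    A: Sequence[str],
    A_prime: Sequence[str],
    a_list: Sequence[Sequence[str]],
    a_prime_list: Sequence[Sequence[str]],
    **meta,
) -> DiscriminationResult:
    """Two-dataset discrimination; strict inequalities, ties incorrect."""
    if len(a_list) != len(a_prime_list):
        raise ValueError(
            f"need equal replicate counts, got {len(a_list)} and {len(a_prime_list)}"
        )
    if not a_list:
        raise ValueError("need at least one sub-dataset ranking per dataset")
    correct = sum(1 for a in a_list if recall(A, a) > recall(A_prime, a))
    correct += sum(1 for ap in a_prime_list if recall(A_prime, ap) > recall(A, ap))
    return DiscriminationResult(correct=correct, total=2 * len(a_list), **meta)


def generalized_discrimination(
    entries: Sequence[tuple[Sequence[str], Sequence[Sequence[str]]]],
    **meta,
) -> DiscriminationResult:
    """Multi-dataset discrimination.

    ``entries`` pairs each dataset's full-data list ``A_j`` with its
    sub-dataset lists; a sub-dataset is correct when its recall against its
    parent strictly exceeds its recall against every other dataset's list.
    """
    if len(entries) < 2:
        raise ValueError("generalized discrimination needs >=2 datasets")
    correct = total = 0
    for j, (A_j, a_lists) in enumerate(entries):
        others = [A for i, (A, _) in enumerate(entries) if i != j]
        for a in a_lists:
            total += 1
            own = recall(A_j, a)
            if all(own > recall(B, a) for B in others):
                correct += 1
    if total == 0:
        raise ValueError("no sub-dataset rankings provided")
    return DiscriminationResult(correct=correct, total=total, **meta)


# ---------------------------------------------------------------------------
# Resampling experiments


def variant_name(cfg: MethodConfig) -> str:
    """Canonical variant label: ora, gsa, gsea, gseas, afc, afcs."""
    if cfg.method in ("gsea", "afc") and cfg.permutation_mode == "sample_label":
        return cfg.method + "s"
    return cfg.method


RankFn = Callable[[ExpressionDataset, int, int], PathwayRanking]


def _as_rank_fn(method) -> tuple[str, RankFn]:
    """Accept an estimator with rank_dataset, or a callable
    (D, K, seed) -> PathwayRanking (used for stub methods in testing)."""
    if hasattr(method, "rank_dataset"):
        name = getattr(
            method, "variant_name", None
        ) or getattr(method, "variant", type(method).__name__.lower())
        return name, lambda D, K, seed: method.rank_dataset(D, K=K, seed=seed)
    if callable(method):
        return getattr(method, "__name__", "stub"), lambda D, K, seed: method(D, K, seed)
    raise TypeError(f"cannot interpret method of type {type(method)!r}")


def _resolve_method(method, coll: GeneSetCollection | None) -> tuple[str, RankFn]:
    if isinstance(method, MethodConfig):
        if coll is None:
            raise ValueError("a gene set collection is required for MethodConfig")
        name = variant_name(method)
        return name, lambda D, K, seed: rank_pathways(D, coll, method, K, seed=seed)
    return _as_rank_fn(method)


def _child_seed(master_seed: int, *keys) -> int:
    return int(derive_seed(master_seed, *keys).generate_state(1)[0] % (2**31))


def _dataset_key(D: ExpressionDataset) -> int:
    """Content fingerprint: identical datasets get identical ranking seeds,
    so a method is a deterministic function of (master seed, data) and two
    bit-identical datasets always produce tying rankings."""
    h = zlib.crc32(np.ascontiguousarray(D.values).tobytes())
    return zlib.crc32("|".join(D.sample_ids).encode(), h)


def _skip_size(method, n: int, N: int, allocation: str) -> str | None:
    if n >= N:
        raise ValueError(f"sub-dataset size {n} must be < N={N}")
    mode = getattr(method, "permutation_mode", None)
    per_cohort = n // 2 if allocation == "balanced" else 2
    if mode == "sample_label" and per_cohort < 3:
        return (
            f"size {n} skipped for sample-label permutation "
            f"(fewer than 3 samples per cohort)"
        )
    return None


def _make_spec(
    D: ExpressionDataset, n: int, allocation: str, seed: int, replicate: int
) -> SubsampleSpec:
    if allocation == "balanced":
        return SubsampleSpec.balanced(n, seed=seed, replicate_index=replicate)
    if allocation == "proportional":
        return SubsampleSpec.proportional(n, D, seed=seed, replicate_index=replicate)
    raise ValueError(f"unknown allocation {allocation!r}")


def run_recall_experiment(
    D: ExpressionDataset,
    coll: GeneSetCollection | None,
    method,
    sizes: Iterable[int],
    M: int,
    K: int,
    master_seed: int,
    dataset_id: str = "D",
    allocation: str = "balanced",
) -> list[RecallResult]:
    """Recall distributions over M stratified sub-datasets per size.

    The full-data ranking A is computed once; each replicate draws a
    sub-dataset, ranks it, and records r(A, a) for both directions.  Sizes
    too small for a sample-label null are skipped with a warning.
    """
    name, rank_fn = _resolve_method(method, coll)
    A = rank_fn(D, K, _child_seed(master_seed, name, "full", _dataset_key(D)))
    results: list[RecallResult] = []
    for n in sizes:
        msg = _skip_size(method, n, D.n_samples, allocation)
        if msg:
            logger.warning("%s: %s", name, msg)
            continue
        sub_seed = _child_seed(master_seed, dataset_id, name, "sub", n)
        per_dir: dict[str, list[float]] = {d: [] for d in DIRECTIONS}
        for i in range(M):
            spec = _make_spec(D, n, allocation, sub_seed, i)
            d = subsample(D, spec)
            a = rank_fn(d, K, _child_seed(master_seed, name, n, i, _dataset_key(d)))
            for direction in DIRECTIONS:
                per_dir[direction].append(
                    recall(A.direction(direction), a.direction(direction))
                )
        for direction in DIRECTIONS:
            results.append(
                RecallResult(
                    method=name,
                    direction=direction,
                    k=K,
                    n=n,
                    recalls=tuple(per_dir[direction]),
                    dataset_id=dataset_id,
                )
            )
    return results


def _subdataset_rankings(
    D: ExpressionDataset,
    rank_fn: RankFn,
    name: str,
    n: int,
    M: int,
    K: int,
    master_seed: int,
    dataset_id: str,
    allocation: str,
) -> list[PathwayRanking]:
    sub_seed = _child_seed(master_seed, dataset_id, name, "sub", n)
    out = []
    for i in range(M):
        spec = _make_spec(D, n, allocation, sub_seed, i)
        d = subsample(D, spec)
        out.append(rank_fn(d, K, _child_seed(master_seed, name, n, i, _dataset_key(d))))
    return out


def run_discrimination_experiment(
    D: ExpressionDataset,
    D_prime: ExpressionDataset,
    coll: GeneSetCollection | None,
    method,
    sizes: Iterable[int],
    M: int,
    K: int,
    master_seed: int,
    dataset_ids: tuple[str, str] = ("D1", "D2"),
    allocation: str = "balanced",
) -> list[DiscriminationResult]:
    """Discrimination between two datasets per sub-dataset size and direction.

    Sub-datasets are drawn independently from each dataset (unmatched pairs).
    """
    name, rank_fn = _resolve_method(method, coll)
    id1, id2 = dataset_ids
    A = rank_fn(D, K, _child_seed(master_seed, name, "full", _dataset_key(D)))
    A_p = rank_fn(
        D_prime, K, _child_seed(master_seed, name, "full", _dataset_key(D_prime))
    )
    results: list[DiscriminationResult] = []
    for n in sizes:
        msg = _skip_size(method, n, min(D.n_samples, D_prime.n_samples), allocation)
        if msg:
            logger.warning("%s: %s", name, msg)
            continue
        a_list = _subdataset_rankings(
            D, rank_fn, name, n, M, K, master_seed, id1, allocation
        )
        ap_list = _subdataset_rankings(
            D_prime, rank_fn, name, n, M, K, master_seed, id2, allocation
        )
        for direction in DIRECTIONS:
            results.append(
                discrimination(
                    A.direction(direction),
                    A_p.direction(direction),
                    [a.direction(direction) for a in a_list],
                    [a.direction(direction) for a in ap_list],
                    method=name,
                    direction=direction,
                    k=K,
                    n=n,
                    dataset_ids=dataset_ids,
                )
            )
    return results


def cross_dataset_overlap(
    D_small: ExpressionDataset,
    D_large: ExpressionDataset,
    coll: GeneSetCollection | None,
    method,
    K: int,
    master_seed: int = 0,
) -> dict[str, float]:
    """Top-K overlap between an independent small and large dataset.

    Equivalent to recall with the large dataset's list as reference; returned
    per direction.  Mirrors comparing separately collected small and large
    studies of the same condition.
    """
    name, rank_fn = _resolve_method(method, coll)
    A_large = rank_fn(
        D_large, K, _child_seed(master_seed, name, "full", _dataset_key(D_large))
    )
    A_small = rank_fn(
        D_small, K, _child_seed(master_seed, name, "full", _dataset_key(D_small))
    )
    return {
        d: recall(A_large.direction(d), A_small.direction(d)) for d in DIRECTIONS
    }
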