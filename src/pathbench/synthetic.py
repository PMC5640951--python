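"""Synthetic two-cohort expression data with controlled pathway perturbation.

The generator emulates the structure of normalized two-cohort microarray
studies: a Gaussian log2-scale baseline per gene, optional equicorrelated
noise shared by genes of the same pathway (co-expression), and additive
log2-scale shifts applied to a designated fraction of the member genes of
chosen pathways in the treatment cohort only.  Under a zero effect size the
two cohorts are exchangeable, which makes the generator a ground truth for
permutation-null calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._rng import derive_rng
from .expression import CONTROL, TREATMENT, ExpressionDataset
from .genesets import GeneSet, GeneSetCollection

__all__ = [
    "Perturbation",
    "SyntheticDesign",
    "block_collection",
    "default_collection",
    "default_design",
    "generate_dataset",
    "generate_benchmark_pair",
]


@dataclass(frozen=True)
class Perturbation:
    """Additive log2-scale shift for one gene set.

    ``delta`` is the shift in log2 units applied to treatment samples;
    ``fraction`` the fraction of member genes affected (chosen by seed);
    ``direction`` is ``up``, ``down`` or ``mixed`` (half +delta, half -delta).
    """

    delta: float
    fraction: float = 1.0
    direction: str = "up"

    def __post_init__(self) -> None:
        if not np.isfinite(self.delta):
            raise ValueError("delta must be finite")
        if not 0.0 < self.fraction <= 1.0:
            raise ValueError("fraction must lie in (0, 1]")
        if self.direction not in ("up", "down", "mixed"):
            raise ValueError(f"unknown direction {self.direction!r}")


@dataclass(frozen=True)
class SyntheticDesign:
    """Full parameterization of the two-cohort generator.

    Defaults model a modest microarray study: 2000 genes, 60 + 60 samples,
    baseline log2 intensity mu = 7 with gene-level noise sigma = 1, and no
    within-pathway correlation (rho = 0).
    """

    n_genes: int = 2000
    n_treatment: int = 60
    n_control: int = 60
    mu: float = 7.0
    sigma: float = 1.0
    rho: float = 0.0
    perturbed: dict[str, Perturbation] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must lie in [0, 1)")
        if self.n_treatment < 2 or self.n_control < 2:
            raise ValueError("each cohort needs >=2 samples")

    @property
    def n_samples(self) -> int:
        return self.n_treatment + self.n_control

    def with_seed(self, seed: int) -> "SyntheticDesign":
        return replace(self, seed=seed)


def block_collection(
    n_genes: int = 2000, n_sets: int = 100, set_size: int = 20
) -> GeneSetCollection:
    """Disjoint block gene sets: set S001 holds genes G0001..G0020, etc."""
    if n_sets * set_size > n_genes:
        raise ValueError("block assignment needs n_sets * set_size <= n_genes")
    gene_ids = [f"G{i + 1:04d}" for i in range(n_genes)]
    sets = []
    for s in range(n_sets):
        members = gene_ids[s * set_size : (s + 1) * set_size]
        sets.append(
            GeneSet(id=f"S{s + 1:03d}", name=f"synthetic block set {s + 1}",
                    genes=frozenset(members))
        )
    return GeneSetCollection(sets=tuple(sets))


def default_collection() -> GeneSetCollection:
    """The fixture collection: 100 disjoint sets of 20 genes over 2000 genes."""
    return block_collection(n_genes=2000, n_sets=100, set_size=20)


def default_design(
    perturbed_ids: tuple[str, ...] = ("S001", "S002"),
    delta: float = 1.0,
    rho: float = 0.0,
    seed: int = 0,
    direction: str = "up",
) -> SyntheticDesign:
    """The fixture design: 2 perturbed sets at delta = 1.0 sigma, 60/60 cohorts."""
    return SyntheticDesign(
        rho=rho,
        perturbed={pid: Perturbation(delta=delta, direction=direction)
                   for pid in perturbed_ids},
        seed=seed,
    )


def _gene_index(coll: GeneSetCollection, gene_ids: list[str]) -> dict[str, int]:
    return {g: i for i, g in enumerate(gene_ids)}


def generate_dataset(
    design: SyntheticDesign, coll: GeneSetCollection
) -> ExpressionDataset:
    """Draw one dataset from the design; bit-identical under the same seed.

    Baseline: gene g, sample j value = mu + sqrt(rho) * f_{s(g), j}
    + sqrt(1 - rho) * eps_{g, j}, with f and eps standard normal scaled by
    sigma and s(g) the first pathway containing g (genes outside every
    pathway are independent).  Perturbed sets then add +/-delta to a
    seed-chosen fraction of member genes in treatment samples; genes in
    several perturbed sets accumulate the sum of shifts.
    """
    unknown = sorted(set(design.perturbed) - set(coll.ids))
    if unknown:
        raise ValueError(f"perturbed set id(s) not in collection: {unknown}")
    G, N = design.n_genes, design.n_samples
    gene_ids = [f"G{i + 1:04d}" for i in range(G)]
    if not set(coll.universe) <= set(gene_ids):
        raise ValueError(
            "collection universe exceeds the designed gene panel; "
            "increase n_genes or use a block collection of matching size"
        )
    rng = derive_rng(design.seed, "synthetic")
    eps = rng.normal(size=(G, N))
    values = design.mu + design.sigma * np.sqrt(1.0 - design.rho) * eps
    if design.rho > 0:
        # one latent factor per pathway and sample; each gene follows the
        # first pathway that contains it
        pos = _gene_index(coll, gene_ids)
        factors = rng.normal(size=(len(coll), N))
        assigned = np.full(G, -1, dtype=int)
        for s, gs in enumerate(coll):
            for g in sorted(gs.genes):
                i = pos[g]
                if assigned[i] < 0:
                    assigned[i] = s
        has = assigned >= 0
        values[has] += (
            design.sigma * np.sqrt(design.rho) * factors[assigned[has]]
        )

    shift = np.zeros(G)
    pos = _gene_index(coll, gene_ids)
    for set_id in sorted(design.perturbed):
        pert = design.perturbed[set_id]
        members = sorted(coll[set_id].genes)
        n_affected = max(1, round(pert.fraction * len(members)))
        pick_rng = derive_rng(design.seed, "perturb", set_id)
        chosen = pick_rng.choice(len(members), size=n_affected, replace=False)
        chosen = np.sort(chosen)
        idx = np.asarray([pos[members[i]] for i in chosen])
        if pert.direction == "up":
            shift[idx] += pert.delta
        elif pert.direction == "down":
            shift[idx] -= pert.delta
        else:  # mixed: first half up, second half down
            half = n_affected // 2
            shift[idx[:half]] += pert.delta
            shift[idx[half:]] -= pert.delta

    treat = np.arange(N) < design.n_treatment
    values[:, treat] += shift[:, None]

    sample_ids = [f"T{j + 1:03d}" for j in range(design.n_treatment)] + [
        f"C{j + 1:03d}" for j in range(design.n_control)
    ]
    cohort = tuple(TREATMENT if t else CONTROL for t in treat)
    return ExpressionDataset(
        gene_ids=tuple(gene_ids),
        sample_ids=tuple(sample_ids),
        values=values,
        cohort=cohort,
    )


def generate_benchmark_pair(
    design_a: SyntheticDesign,
    design_b: SyntheticDesign,
    coll: GeneSetCollection,
) -> tuple[ExpressionDataset, ExpressionDataset]:
    """Two datasets over a shared gene universe and collection — the setting
    for discrimination (typically with disjoint perturbed-set groups)."""
    if design_a.n_genes != design_b.n_genes:
        raise ValueError(
            f"designs must share the gene panel, got n_genes "
            f"{design_a.n_genes} and {design_b.n_genes}"
        )
    return generate_dataset(design_a, coll), generate_dataset(design_b, coll)
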