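"""Two-cohort expression datasets and stratified resampling.

The central object is :class:`ExpressionDataset`: a genes × samples matrix of
log2-scale expression values with each sample assigned to a *treatment* or
*control* cohort.  The same type holds both an original dataset ``D`` of ``N``
samples and the sub-datasets ``d`` of ``n`` samples drawn from it without
replacement — resampling selects columns, it never recomputes values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import comb
from pathlib import Path

import numpy as np
import pandas as pd

from ._rng import derive_rng

__all__ = [
    "TREATMENT",
    "CONTROL",
    "ExpressionDataset",
    "SubsampleSpec",
    "read_expression",
    "read_phenotype",
    "write_expression",
    "subsample",
    "count_distinct_label_assignments",
]

logger = logging.getLogger(__name__)

TREATMENT = "treatment"
CONTROL = "control"


@dataclass(frozen=True)
class ExpressionDataset:
    """Log2 expression matrix (genes × samples) with a binary cohort label.

    Invariants: matrix dimensions match the id lists, gene ids are unique,
    there are no missing values, and each cohort has at least two samples.
    """

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray
    cohort: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        object.__setattr__(self, "cohort", tuple(self.cohort))
        n_g, n_s = len(self.gene_ids), len(self.sample_ids)
        if values.shape != (n_g, n_s):
            raise ValueError(
                f"matrix shape {values.shape} does not match "
                f"{n_g} genes x {n_s} samples"
            )
        if len(self.cohort) != n_s:
            raise ValueError("cohort assignment length does not match sample count")
        bad = sorted(set(self.cohort) - {TREATMENT, CONTROL})
        if bad:
            raise ValueError(f"unknown cohort label(s): {bad}")
        if len(set(self.gene_ids)) != n_g:
            seen: set[str] = set()
            dupes = [g for g in self.gene_ids if g in seen or seen.add(g)]
            raise ValueError(f"duplicate gene id(s): {sorted(set(dupes))}")
        if np.isnan(values).any():
            raise ValueError("expression matrix contains missing values")
        if self.n_treatment < 2 or self.n_control < 2:
            raise ValueError(
                f"each cohort needs >=2 samples, got {self.n_treatment} treatment "
                f"/ {self.n_control} control"
            )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def treatment_mask(self) -> np.ndarray:
        return np.asarray([c == TREATMENT for c in self.cohort])

    @property
    def n_treatment(self) -> int:
        return int(self.treatment_mask.sum())

    @property
    def n_control(self) -> int:
        return self.n_samples - self.n_treatment

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.gene_ids), columns=list(self.sample_ids)
        )

    def select_samples(self, indices: np.ndarray) -> "ExpressionDataset":
        """Column selection; values are copied bit-exactly, never recomputed."""
        indices = np.asarray(indices, dtype=int)
        return ExpressionDataset(
            gene_ids=self.gene_ids,
            sample_ids=tuple(self.sample_ids[i] for i in indices),
            values=self.values[:, indices],
            cohort=tuple(self.cohort[i] for i in indices),
        )


@dataclass(frozen=True)
class SubsampleSpec:
    """One stratified draw: cohort allocation, master seed, replicate index."""

    n_treatment: int
    n_control: int
    seed: int
    replicate_index: int = 0

    def __post_init__(self) -> None:
        if self.n_treatment < 2 or self.n_control < 2:
            raise ValueError("sub-dataset needs >=2 samples per cohort")

    @property
    def n(self) -> int:
        return self.n_treatment + self.n_control

    @classmethod
    def balanced(cls, n: int, seed: int, replicate_index: int = 0) -> "SubsampleSpec":
        """Equal split n/2 + n/2 (n must be even)."""
        if n % 2:
            raise ValueError(f"balanced allocation requires even n, got {n}")
        return cls(n // 2, n // 2, seed=seed, replicate_index=replicate_index)

    @classmethod
    def proportional(
        cls, n: int, dataset: ExpressionDataset, seed: int, replicate_index: int = 0
    ) -> "SubsampleSpec":
        """Allocate proportionally to the parent's cohort sizes (rounded),
        keeping at least two samples per cohort."""
        n_t = round(n * dataset.n_treatment / dataset.n_samples)
        n_t = min(max(n_t, 2), n - 2)
        return cls(n_t, n - n_t, seed=seed, replicate_index=replicate_index)


def subsample(D: ExpressionDataset, spec: SubsampleSpec) -> ExpressionDataset:
    """Draw a stratified sub-dataset: uniform sampling without replacement
    within each cohort, deterministic under (seed, replicate_index)."""
    if spec.n >= D.n_samples:
        raise ValueError(f"sub-dataset size {spec.n} must be < N={D.n_samples}")
    t_idx = np.flatnonzero(D.treatment_mask)
    c_idx = np.flatnonzero(~D.treatment_mask)
    if spec.n_treatment > t_idx.size:
        raise ValueError(
            f"requested {spec.n_treatment} treatment samples, only {t_idx.size} available"
        )
    if spec.n_control > c_idx.size:
        raise ValueError(
            f"requested {spec.n_control} control samples, only {c_idx.size} available"
        )
    rng = derive_rng(spec.seed, "subsample", spec.replicate_index)
    chosen_t = rng.choice(t_idx, size=spec.n_treatment, replace=False)
    chosen_c = rng.choice(c_idx, size=spec.n_control, replace=False)
    return D.select_samples(np.sort(np.concatenate([chosen_t, chosen_c])))


def count_distinct_label_assignments(n1: int, n2: int) -> int:
    """Number of distinct two-cohort label assignments of n1+n2 samples.

    When the cohorts have equal size, an assignment and its complement produce
    the same two-group split, so the count is C(n1+n2, n1)/2 — e.g. 10 distinct
    assignments for 3 treatment vs 3 control samples.
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("cohort sizes must be >=1")
    total = comb(n1 + n2, n1)
    return total // 2 if n1 == n2 else total


# ---------------------------------------------------------------------------
# I/O: tab-delimited matrix + CLS or two-column phenotype files


def read_phenotype(path: str | Path, sample_ids: list[str] | None = None) -> dict[str, str]:
    """Read a phenotype file mapping sample id -> cohort label.

    Two dialects are supported:

    * GSEA CLS: three lines (``N k 1`` / ``# name1 name2`` / per-sample class
      tokens in matrix column order).  The first declared class is treatment.
      Requires ``sample_ids`` to pair tokens with samples.
    * Two-column TSV: ``sample_id<TAB>label`` with labels ``treatment`` /
      ``control`` (case-insensitive).
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if path.suffix.lower() == ".cls" or (lines and _looks_like_cls(lines)):
        return _parse_cls(lines, sample_ids)
    mapping: dict[str, str] = {}
    for lineno, ln in enumerate(lines, start=1):
        fields = ln.split("\t")
        if len(fields) != 2:
            raise ValueError(f"phenotype line {lineno}: expected 2 tab-separated fields")
        sid, label = fields[0].strip(), fields[1].strip().lower()
        if label not in (TREATMENT, CONTROL):
            raise ValueError(
                f"phenotype line {lineno}: unknown cohort label {fields[1]!r}"
            )
        if sid in mapping:
            raise ValueError(f"phenotype line {lineno}: duplicate sample id {sid!r}")
        mapping[sid] = label
    return mapping


def _looks_like_cls(lines: list[str]) -> bool:
    head = lines[0].split()
    return len(head) == 3 and all(tok.lstrip("-").isdigit() for tok in head)


def _parse_cls(lines: list[str], sample_ids: list[str] | None) -> dict[str, str]:
    if sample_ids is None:
        raise ValueError("CLS phenotype files require the matrix sample order")
    if len(lines) < 3:
        raise ValueError("CLS file needs 3 non-empty lines")
    n_declared = int(lines[0].split()[0])
    names = lines[1].lstrip("#").split()
    tokens = lines[2].split()
    if len(tokens) != len(sample_ids) or n_declared != len(sample_ids):
        raise ValueError(
            f"CLS declares {n_declared} samples with {len(tokens)} tokens; "
            f"matrix has {len(sample_ids)}"
        )
    classes = list(dict.fromkeys(tokens))  # order of first appearance
    if len(classes) != 2:
        raise ValueError(f"CLS file must define exactly 2 classes, got {classes}")
    # Numeric CLS tokens (0/1) refer to class order in the name line; symbolic
    # tokens are matched by first appearance. First class is treatment.
    if set(classes) <= {"0", "1"} and len(names) == 2:
        first = "0"
    else:
        first = classes[0]
    return {
        sid: (TREATMENT if tok == first else CONTROL)
        for sid, tok in zip(sample_ids, tokens)
    }


def read_expression(
    matrix_path: str | Path, phenotype_path: str | Path
) -> ExpressionDataset:
    """Read a genes × samples TSV (header = sample ids, first column = gene ids)
    plus a phenotype file; every matrix sample must have a cohort label."""
    df = pd.read_csv(matrix_path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dupes = sorted(set(df.index[df.index.duplicated()]))
        raise ValueError(f"duplicated gene row(s) in matrix: {dupes}")
    sample_ids = [str(c) for c in df.columns]
    mapping = read_phenotype(phenotype_path, sample_ids=sample_ids)
    missing = [s for s in sample_ids if s not in mapping]
    if missing:
        raise ValueError(f"phenotype file missing sample(s): {missing}")
    cohort = tuple(mapping[s] for s in sample_ids)
    return ExpressionDataset(
        gene_ids=tuple(str(g) for g in df.index),
        sample_ids=tuple(sample_ids),
        values=df.to_numpy(dtype=float),
        cohort=cohort,
    )


def write_expression(
    D: ExpressionDataset, matrix_path: str | Path, phenotype_path: str | Path
) -> None:
    """Write the matrix as TSV and the phenotype as CLS (treatment first)."""
    D.to_frame().to_csv(matrix_path, sep="\t", index_label="gene")
    with open(phenotype_path, "w", encoding="utf-8") as fh:
        fh.write(f"{D.n_samples} 2 1\n# treatment control\n")
        fh.write(" ".join("0" if c == TREATMENT else "1" for c in D.cohort) + "\n")
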