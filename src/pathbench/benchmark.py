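"""Configuration-driven benchmark runs: simulate → rank → evaluate → report.

A :class:`BenchmarkConfig` (usually loaded from YAML) names the datasets
(files or synthetic designs), the gene-set collection, the method variants,
and the experimental grid (sub-dataset sizes, replicate count M, list lengths
K).  :func:`run_benchmark` produces tidy CSV tables plus a JSON summary and is
deterministic under the master seed; replicates are independent work units
keyed by replicate index, so results do not depend on execution order.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .expression import ExpressionDataset, read_expression
from .genesets import GeneSetCollection, filter_by_size, read_gmt
from .metrics import (
    run_discrimination_experiment,
    run_recall_experiment,
    variant_name,
)
from .pa_methods import method_config
from .synthetic import Perturbation, SyntheticDesign, block_collection, generate_dataset

__all__ = [
    "BenchmarkConfig",
    "BenchmarkError",
    "design_from_dict",
    "run_benchmark",
    "summarize",
]

logger = logging.getLogger(__name__)


class BenchmarkError(RuntimeError):
    """A benchmark stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class BenchmarkConfig:
    """The full experimental grid for one benchmark run."""

    datasets: list[dict]
    collection: dict
    methods: list[dict]
    sizes: list[int] = field(default_factory=lambda: [6, 12, 24, 48])
    M: int = 500
    k_values: list[int] = field(default_factory=lambda: [20, 50])
    seed: int = 0
    allocation: str = "balanced"
    output_dir: str = "results"

    def __post_init__(self) -> None:
        if not self.datasets:
            raise ValueError("config needs at least one dataset")
        if not self.methods:
            raise ValueError("config needs at least one method")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "BenchmarkConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        methods = [
            {"name": m} if isinstance(m, str) else dict(m)
            for m in raw.get("methods", [])
        ]
        return cls(
            datasets=[dict(d) for d in raw.get("datasets", [])],
            collection=dict(raw.get("collection", {})),
            methods=methods,
            sizes=list(raw.get("sizes", [6, 12, 24, 48])),
            M=int(raw.get("M", 500)),
            k_values=list(raw.get("k_values", [20, 50])),
            seed=int(raw.get("seed", 0)),
            allocation=str(raw.get("allocation", "balanced")),
            output_dir=str(raw.get("output_dir", "results")),
        )


def design_from_dict(spec: dict) -> SyntheticDesign:
    """Build a SyntheticDesign from a plain dict (YAML-friendly)."""
    spec = dict(spec)
    perturbed = {
        pid: Perturbation(**p) if isinstance(p, dict) else Perturbation(delta=float(p))
        for pid, p in (spec.pop("perturbed", {}) or {}).items()
    }
    return SyntheticDesign(perturbed=perturbed, **spec)


def _load_collection(spec: dict) -> GeneSetCollection:
    if "gmt" in spec:
        coll = read_gmt(spec["gmt"])
    elif "blocks" in spec:
        coll = block_collection(**spec["blocks"])
    else:
        raise ValueError("collection spec needs a 'gmt' path or a 'blocks' design")
    if "min_size" in spec or "max_size" in spec:
        coll = filter_by_size(
            coll, int(spec.get("min_size", 1)), int(spec.get("max_size", 10**9))
        )
    return coll


def _load_dataset(spec: dict, coll: GeneSetCollection) -> tuple[str, ExpressionDataset]:
    if "synthetic" in spec:
        design = design_from_dict(spec["synthetic"])
        return spec["id"], generate_dataset(design, coll)
    return spec["id"], read_expression(spec["matrix"], spec["phenotype"])


def run_benchmark(cfg: BenchmarkConfig, output_dir: str | Path | None = None) -> dict:
    """Run the full grid; write recall.csv, discrimination.csv, summary.json.

    Returns the summary dict.  Partial results are flushed before a failing
    stage raises, so completed tables survive an abort.
    """
    out = Path(output_dir if output_dir is not None else cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    try:
        coll = _load_collection(cfg.collection)
    except Exception as e:  # noqa: BLE001 - re-raise with stage name
        raise BenchmarkError("collection", str(e)) from e

    datasets: list[tuple[str, ExpressionDataset]] = []
    for spec in cfg.datasets:
        try:
            datasets.append(_load_dataset(spec, coll))
        except Exception as e:
            raise BenchmarkError("dataset", f"{spec.get('id', '?')}: {e}") from e

    recall_rows: list[dict] = []
    disc_rows: list[dict] = []
    try:
        for mspec, K in itertools.product(cfg.methods, cfg.k_values):
            mspec = dict(mspec)
            name = mspec.pop("name")
            mcfg = method_config(name, **mspec)
            for ds_id, D in datasets:
                for res in run_recall_experiment(
                    D, coll, mcfg, cfg.sizes, cfg.M, K, cfg.seed,
                    dataset_id=ds_id, allocation=cfg.allocation,
                ):
                    for i, r in enumerate(res.recalls):
                        recall_rows.append(
                            {"method": res.method, "metric": "recall",
                             "direction": res.direction, "K": res.k, "n": res.n,
                             "dataset": ds_id, "replicate": i, "value": r}
                        )
            for (id1, D1), (id2, D2) in itertools.combinations(datasets, 2):
                for res in run_discrimination_experiment(
                    D1, D2, coll, mcfg, cfg.sizes, cfg.M, K, cfg.seed,
                    dataset_ids=(id1, id2), allocation=cfg.allocation,
                ):
                    disc_rows.append(
                        {"method": res.method, "metric": "discrimination",
                         "direction": res.direction, "K": res.k, "n": res.n,
                         "dataset_a": id1, "dataset_b": id2,
                         "correct": res.correct, "total": res.total,
                         "value": res.s}
                    )
    except Exception as e:
        _flush(out, recall_rows, disc_rows)
        if isinstance(e, BenchmarkError):
            raise
        raise BenchmarkError("evaluate", str(e)) from e

    _flush(out, recall_rows, disc_rows)
    summary = _summary_dict(recall_rows, disc_rows, cfg)
    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    logger.info("benchmark complete: %d recall rows, %d discrimination rows",
                len(recall_rows), len(disc_rows))
    return summary


_RECALL_COLS = ["method", "metric", "direction", "K", "n", "dataset",
                "replicate", "value"]
_DISC_COLS = ["method", "metric", "direction", "K", "n", "dataset_a",
              "dataset_b", "correct", "total", "value"]


def _flush(out: Path, recall_rows: list[dict], disc_rows: list[dict]) -> None:
    pd.DataFrame(recall_rows, columns=_RECALL_COLS).to_csv(
        out / "recall.csv", index=False
    )
    pd.DataFrame(disc_rows, columns=_DISC_COLS).to_csv(
        out / "discrimination.csv", index=False
    )


def _summary_dict(recall_rows, disc_rows, cfg: BenchmarkConfig) -> dict:
    summary: dict = {"seed": cfg.seed, "M": cfg.M, "mean_recall": [],
                     "discrimination": []}
    if recall_rows:
        df = pd.DataFrame(recall_rows)
        grouped = df.groupby(
            ["dataset", "method", "direction", "K", "n"], as_index=False
        )["value"].mean()
        summary["mean_recall"] = grouped.to_dict(orient="records")
    if disc_rows:
        summary["discrimination"] = [
            {k: row[k] for k in
             ("method", "direction", "K", "n", "dataset_a", "dataset_b", "value")}
            for row in disc_rows
        ]
    return summary


def summarize(results_dir: str | Path) -> dict:
    """Mean-recall matrices (sizes × methods) with row-wise max/min flags.

    Returns ``{(dataset, direction, K): {"mean": DataFrame, "is_max": ...,
    "is_min": ...}}``; ties flag every tied cell.
    """
    results_dir = Path(results_dir)
    path = results_dir / "recall.csv"
    if not path.exists():
        raise FileNotFoundError(f"no recall.csv under {results_dir}")
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path} holds no results")
    out: dict = {}
    for (dataset, direction, K), sub in df.groupby(["dataset", "direction", "K"]):
        mean = sub.pivot_table(
            index="n", columns="method", values="value", aggfunc="mean"
        )
        row_max = mean.max(axis=1)
        row_min = mean.min(axis=1)
        out[(dataset, direction, int(K))] = {
            "mean": mean,
            "is_max": mean.eq(row_max, axis=0),
            "is_min": mean.eq(row_min, axis=0),
        }
    return out
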