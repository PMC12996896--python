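"""Benchmark orchestration: throughput measurement and multi-task runs.

Wall-clock throughput is reported for context only — it depends on the
machine, the language and the vectorization strategy, so it is quarantined
in its own column group and never compared against published figures.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .audit import count_collisions
from .datasets import random_kmers, similar_chain, synthetic_genome, window_kmers
from .registry import HashConfig, hash_batch, parse_label
from .stats import DEFAULT_BUCKET_PANEL, avalanche, uniformity_panel

__all__ = ["BenchmarkRun", "measure_throughput", "run_benchmark"]

logger = logging.getLogger("gencrc32")

TASKS = ("audit", "uniformity", "avalanche", "throughput")


@dataclass
class BenchmarkRun:
    """Specification of one reproducible benchmark run."""

    configs: list[str]
    tasks: list[str] = field(default_factory=lambda: list(TASKS))
    k_values: list[int] = field(default_factory=lambda: list(range(4, 13)))
    k_eval: int = 16
    n: int = 1_000_000
    seed: int = 0
    mutants_per_origin: int = 3
    out_dir: str = "benchmark_out"
    fasta: str | None = None
    m_panel: tuple[int, ...] = DEFAULT_BUCKET_PANEL

    def __post_init__(self) -> None:
        unknown = set(self.tasks) - set(TASKS)
        if unknown:
            raise ValueError(f"unknown tasks: {sorted(unknown)}")


def measure_throughput(
    config: HashConfig, k: int, n: int = 1_000_000, seed: int = 0
) -> float:
    """Hashes per second over n random k-mers (warm run, wall clock)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    kmers = random_kmers(n, k, seed=seed, as_array=True)
    hash_batch(config, kmers)  # warm-up: tables, caches
    t0 = time.perf_counter()
    hash_batch(config, kmers)
    elapsed = time.perf_counter() - t0
    return n / max(elapsed, 1e-12)


def run_benchmark(run: BenchmarkRun) -> dict[str, Path]:
    """Execute the requested tasks for every config and write TSV/JSON reports.

    Outputs (in ``run.out_dir``): ``manifest.json`` with every parameter and
    seed, ``collisions.tsv`` (config x k collision table), and
    ``metrics.tsv`` (per-config uniformity p values, mean flip, throughput).
    Per-task failures are recorded in the manifest; any failure raises after
    all tasks were attempted.
    """
    out = Path(run.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    configs = [parse_label(lbl) for lbl in run.configs]
    failures: list[str] = []
    written: dict[str, Path] = {}

    if "audit" in run.tasks:
        rows = []
        for cfg in configs:
            for k in run.k_values:
                logger.info("audit %s k=%d", cfg.label, k)
                try:
                    rows.append(count_collisions(cfg, k).to_dict())
                except Exception as exc:  # noqa: BLE001
                    failures.append(f"audit {cfg.label} k={k}: {exc}")
        if rows:
            path = out / "collisions.tsv"
            pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
            written["collisions"] = path

    need_eval = {"uniformity", "avalanche", "throughput"} & set(run.tasks)
    if need_eval:
        datasets: dict[str, np.ndarray] = {}
        if "uniformity" in run.tasks or "avalanche" in run.tasks:
            datasets["random"] = random_kmers(run.n, run.k_eval, seed=run.seed, as_array=True)
        if "uniformity" in run.tasks:
            datasets["similar"] = similar_chain(run.n, run.k_eval, seed=run.seed + 1, as_array=True)
            fasta = run.fasta
            if fasta is None:
                fasta = str(out / "synthetic_genome.fa")
                synthetic_genome(fasta, seed=run.seed + 2)
            datasets["window"] = window_kmers(fasta, run.k_eval, run.n, as_array=True)
        rows = []
        for cfg in configs:
            logger.info("evaluate %s", cfg.label)
            row: dict = {"config_label": cfg.label}
            try:
                if "uniformity" in run.tasks:
                    for name in ("random", "similar", "window"):
                        _, p = uniformity_panel(cfg, datasets[name], run.m_panel, dataset=name)
                        row[f"p_{name}"] = round(p, 4)
                if "avalanche" in run.tasks:
                    rep = avalanche(
                        cfg, datasets["random"], run.mutants_per_origin,
                        rng=np.random.default_rng(run.seed + 3),
                    )
                    row["mean_flip"] = round(rep.mean_flip, 4)
                if "throughput" in run.tasks:
                    rate = measure_throughput(cfg, run.k_eval, run.n, seed=run.seed)
                    # hardware-dependent: not comparable across machines
                    row["speed_mh_per_s_hardware_dependent"] = round(rate / 1e6, 2)
            except Exception as exc:  # noqa: BLE001
                failures.append(f"evaluate {cfg.label}: {exc}")
            rows.append(row)
        path = out / "metrics.tsv"
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        written["metrics"] = path

    manifest = {
        "tool": "gencrc32",
        "version": __version__,
        "run": asdict(run),
        "outputs": {k: str(v) for k, v in written.items()},
        "failures": failures,
    }
    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, default=str))
    written["manifest"] = mpath
    for name, path in written.items():
        logger.info("wrote %s: %s", name, path)
    if failures:
        raise RuntimeError(f"{len(failures)} task(s) failed; see manifest {mpath}")
    return written
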