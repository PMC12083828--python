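"""Experiment sweeps: many (dataset, algorithm, run) combinations with
reproducible per-run seeds, JSON results, and a manifest."""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .data import OptimizerConfig, RunResult, load_dataset
from .search import VARIANT_TOGGLES, run_variant


@dataclass(frozen=True)
class ExperimentConfig:
    """A sweep: each algorithm runs ``runs`` times on each dataset."""

    datasets: tuple
    algorithms: tuple
    runs: int = 10
    seed: int = 0
    out_dir: str = "results"
    optimizer: OptimizerConfig = field(default_factory=OptimizerConfig)

    def __post_init__(self):
        if self.runs < 1:
            raise ValueError("runs must be >= 1")
        unknown = [a for a in self.algorithms if a not in VARIANT_TOGGLES]
        if unknown:
            raise ValueError(
                f"unknown algorithm(s) {unknown}; expected names from "
                f"{sorted(VARIANT_TOGGLES)}"
            )

    @staticmethod
    def from_yaml(path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        opt = OptimizerConfig(**raw.get("optimizer", {}))
        return ExperimentConfig(
            datasets=tuple(raw["datasets"]),
            algorithms=tuple(raw["algorithms"]),
            runs=int(raw.get("runs", 10)),
            seed=int(raw.get("seed", 0)),
            out_dir=str(raw.get("out_dir", "results")),
            optimizer=opt,
        )


def derive_seed(master_seed: int, dataset_idx: int, algo_idx: int, run_idx: int) -> int:
    """Pure function of the run coordinates; no global RNG state involved."""
    ss = np.random.SeedSequence([int(master_seed), dataset_idx, algo_idx, run_idx])
    return int(ss.generate_state(1)[0] % (2**31))


def _config_hash(config: ExperimentConfig) -> str:
    payload = json.dumps(
        {
            "datasets": list(config.datasets),
            "algorithms": list(config.algorithms),
            "runs": config.runs,
            "seed": config.seed,
            "optimizer": vars(config.optimizer),
        },
        sort_keys=True,
        default=str,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_experiment(config: ExperimentConfig) -> Path:
    """Execute the sweep; one RunResult JSON per (dataset, algorithm, run)
    plus a manifest.  Per-run failures are recorded without aborting."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config_hash": _config_hash(config),
        "python": sys.version.split()[0],
        "numpy": np.__version__,
        "master_seed": config.seed,
        "runs": [],
        "failures": [],
    }
    for di, ds_path in enumerate(config.datasets):
        dataset = load_dataset(ds_path)
        for ai, algo in enumerate(config.algorithms):
            for ri in range(config.runs):
                seed = derive_seed(config.seed, di, ai, ri)
                opt = OptimizerConfig(**{**vars(config.optimizer), "seed": seed})
                fname = f"{dataset.name}__{algo}__run{ri}.json"
                try:
                    result = run_variant(dataset, algo, opt)
                except Exception as exc:  # record and continue the sweep
                    manifest["failures"].append(
                        {"dataset": dataset.name, "algorithm": algo, "run": ri,
                         "error": repr(exc)}
                    )
                    continue
                payload = result.to_dict()
                payload["dataset"] = dataset.name
                payload["algorithm"] = algo
                payload["run"] = ri
                payload["derived_seed"] = seed
                (out / fname).write_text(json.dumps(payload, indent=1))
                manifest["runs"].append(
                    {"file": fname, "dataset": dataset.name, "algorithm": algo,
                     "run": ri, "seed": seed, "runtime_s": result.runtime_s}
                )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out


def load_results(results_dir) -> list:
    """Read every per-run JSON in a results directory (manifest excluded)."""
    records = []
    for path in sorted(Path(results_dir).glob("*.json")):
        if path.name == "manifest.json":
            continue
        d = json.loads(path.read_text())
        d["result"] = RunResult.from_dict(d)
        records.append(d)
    return records
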