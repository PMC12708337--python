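"""Run configuration, seeding and stage orchestration.

A :class:`RunConfig` captures everything a run needs — the simulation
scenario (or an input NEXUS path), the test battery knobs, and the
output directory — and :func:`run` executes the requested stages in
dependency order, writing TSV/JSON artifacts plus a manifest that
fully determines every number in the outputs.

Per-stage seeds are derived from the master seed with named
``SeedSequence`` spawn keys, so toggling one stage never shifts the
random streams of another.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import io as mio
from .gradient import gradient_report
from .io import read_nexus
from .layout import DEFAULT_CATEGORY_MAP, vertebrate_layout, insect_layout
from .simulate import SimulationScenario, generate_dataset, write_dataset
from .toptests import TestConfig
from .workflows import (
    antigene_matrices,
    category_matrix,
    congruent_proportion,
    pairwise_matrix,
    subsample_experiment,
)

logger = logging.getLogger(__name__)

STAGES = (
    "simulate", "pairwise", "antigene", "categories", "subsample",
    "gradient",
)

PROFILES = {
    # B replicates, ILD permutations, search restarts, model-rate fits
    "ci": dict(b_reps=1000, ild_permutations=99, restarts=1,
               optimize_rates=False, final_rounds=1),
    "desk": dict(b_reps=10000, ild_permutations=99, restarts=3,
                 optimize_rates=True, final_rounds=3),
    "full": dict(b_reps=10000, ild_permutations=999, restarts=3,
                 optimize_rates=True, final_rounds=4),
}


@dataclass
class RunConfig:
    out_dir: str = "out"
    stages: Sequence[str] = ("simulate", "pairwise")
    seed: int = 0
    profile: str = "ci"
    # inputs: either a NEXUS path or a simulation scenario
    input_nexus: Optional[str] = None
    scenario: SimulationScenario = field(
        default_factory=SimulationScenario
    )
    alpha: float = 0.05
    genes: Optional[Sequence[str]] = None
    fractions: Sequence[float] = (1.0, 0.5, 0.25, 0.10)
    gradient_test: str = "p_au"
    overwrite: bool = False

    def __post_init__(self):
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ValueError(f"unknown stages: {unknown}")
        if self.profile not in PROFILES:
            raise ValueError(f"unknown profile {self.profile!r}")

    def test_config(self) -> TestConfig:
        prof = PROFILES[self.profile]
        return TestConfig(alpha=self.alpha, **prof)

    def stage_seed(self, stage: str) -> int:
        key = STAGES.index(stage)
        ss = np.random.SeedSequence(self.seed, spawn_key=(key,))
        return int(ss.generate_state(1)[0] % (2**31))

    def to_manifest(self) -> dict:
        d = dataclasses.asdict(self)
        d["scenario"]["model"] = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in dataclasses.asdict(self.scenario.model).items()
        }
        blob = json.dumps(d, sort_keys=True, default=str)
        return {
            "config": d,
            "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        }


def run(config: RunConfig) -> Path:
    """Execute the configured stages; returns the artifact directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=config.overwrite or True)
    manifest = config.to_manifest()
    manifest["started"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest["stages"] = {}
    cfg = config.test_config()

    dataset = None
    layout = None
    try:
        if config.input_nexus:
            dataset = read_nexus(config.input_nexus)
            tmpl = config.scenario.layout_template
            layout = (
                insect_layout() if tmpl == "insect" else vertebrate_layout()
            )
        for stage in config.stages:
            t0 = time.time()
            stage_dir = out / stage
            stage_dir.mkdir(exist_ok=True)
            seed = config.stage_seed(stage)
            if stage == "simulate":
                if config.input_nexus:
                    continue  # real data supplied; nothing to simulate
                ds = generate_dataset(config.scenario)
                write_dataset(ds, stage_dir, overwrite=config.overwrite)
                dataset, layout = ds.data, ds.layout
            elif stage == "pairwise":
                matrix = pairwise_matrix(
                    _need(dataset), cfg, seed=seed, genes=config.genes
                )
                mio.write_tsv(
                    matrix.long_rows(), stage_dir / "pairwise_long.tsv"
                )
                mio.write_json(
                    {
                        t: congruent_proportion(matrix, t)
                        for t in matrix.tests()
                    },
                    stage_dir / "congruent_proportion.json",
                )
                manifest["stages"]["pairwise_matrix"] = len(matrix.cells)
                if "gradient" in config.stages:
                    manifest["_pairwise_matrix_obj"] = matrix
            elif stage == "antigene":
                anti = antigene_matrices(_need(dataset), cfg, seed=seed)
                rows = []
                for g, row in anti.rows.items():
                    for h, cell in row.items():
                        for t, dec in cell.items():
                            rows.append(
                                {
                                    "removed_gene": g,
                                    "gene": h,
                                    "test": t,
                                    "call": dec.call,
                                }
                            )
                mio.write_tsv(rows, stage_dir / "antigene_long.tsv")
            elif stage == "categories":
                cmat = category_matrix(
                    _need(dataset), DEFAULT_CATEGORY_MAP, cfg, seed=seed
                )
                mio.write_tsv(
                    cmat.long_rows(), stage_dir / "categories_long.tsv"
                )
            elif stage == "subsample":
                reports = subsample_experiment(
                    _need(dataset), config.fractions, cfg, seed=seed,
                    genes=config.genes,
                )
                rows = []
                for rep in reports:
                    for t, v in rep.congruent_proportion.items():
                        rows.append(
                            {
                                "fraction": rep.fraction,
                                "n_taxa": len(rep.retained_taxa),
                                "test": t,
                                "congruent_proportion": v,
                            }
                        )
                mio.write_tsv(rows, stage_dir / "subsample.tsv")
            elif stage == "gradient":
                matrix = manifest.pop("_pairwise_matrix_obj", None)
                if matrix is None:
                    matrix = pairwise_matrix(
                        _need(dataset), cfg,
                        seed=config.stage_seed("pairwise"),
                        genes=config.genes,
                    )
                rows = gradient_report(
                    _need(layout), matrix, config.gradient_test
                )
                mio.write_tsv(rows, stage_dir / "gradient.tsv")
            manifest["stages"][stage] = {
                "seed": seed,
                "wall_seconds": round(time.time() - t0, 2),
            }
    except Exception as exc:
        manifest["failed_at"] = str(exc)
        manifest.pop("_pairwise_matrix_obj", None)
        mio.write_json(manifest, out / "manifest.json")
        raise
    manifest.pop("_pairwise_matrix_obj", None)
    mio.write_json(manifest, out / "manifest.json")
    return out


def _need(obj):
    if obj is None:
        raise ValueError(
            "stage requires a dataset; run 'simulate' first or pass "
            "--input-nexus"
        )
    return obj
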