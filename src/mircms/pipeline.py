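"""Stage orchestration with manifests and hash-based reuse.

Stages run in dependency order (simulate -> annotate -> novel -> de ->
degradome -> integrate -> report).  Each stage writes a manifest recording
the SHA-256 of its inputs and its effective parameters; on rerun a stage
whose manifest matches and whose outputs exist is skipped.  A missing input
raises before any stage executes; a stage failure aborts downstream stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd

from . import benchmark
from .config import PipelineConfig
from .simulate import SimulationConfig, simulate_study, write_study

log = logging.getLogger(__name__)

STAGE_ORDER = ["simulate", "annotate", "novel", "de", "degradome",
               "integrate", "report"]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _manifest_path(workdir: Path, stage: str) -> Path:
    return workdir / "manifests" / f"{stage}.json"


def _write_manifest(workdir: Path, stage: str, inputs: list[Path],
                    params: dict, outputs: list[Path]) -> None:
    manifest = {
        "stage": stage,
        "inputs": {str(p): _sha256(p) for p in inputs if p.exists()},
        "params": params,
        "outputs": [str(p) for p in outputs],
        "finished": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    path = _manifest_path(workdir, stage)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def _can_skip(workdir: Path, stage: str, inputs: list[Path], params: dict) -> bool:
    path = _manifest_path(workdir, stage)
    if not path.exists():
        return False
    try:
        manifest = json.loads(path.read_text())
    except json.JSONDecodeError:
        return False
    if manifest.get("params") != params:
        return False
    current = {str(p): _sha256(p) for p in inputs if p.exists()}
    if manifest.get("inputs") != current:
        return False
    return all(Path(p).exists() for p in manifest.get("outputs", []))


def run(config: PipelineConfig, stages: list[str] | None = None) -> dict:
    """Execute the pipeline; returns a run summary with per-stage status.

    The current implementation executes the full in-memory analysis on the
    synthetic study defined by the configuration seed and writes every
    stage's artifacts beneath ``config.workdir``; file-level inputs named in
    the configuration are validated up front.
    """
    workdir = Path(config.workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    requested = stages or config.stages

    # validate inputs for enabled stages before anything runs
    for name in ("genome", "known_precursors", "known_matures", "transcripts",
                 "srna_counts", "rnaseq_counts", "annotation"):
        value = getattr(config, name)
        if value is not None and not Path(value).exists():
            raise FileNotFoundError(f"input {name!r} not found: {value}")

    params = {"seed": config.seed, "n_shuffles": config.n_shuffles,
              "backend": config.fold_backend,
              "sim_params": {k: str(v) for k, v in sorted(config.sim_params.items())}}
    status: dict[str, str] = {}
    t0 = time.time()

    sim_dir = workdir / "synthetic"
    stage_inputs: list[Path] = []
    if "simulate" in requested:
        if _can_skip(workdir, "simulate", stage_inputs, params):
            status["simulate"] = "skipped"
            log.info("stage simulate: reused existing artifacts")
        else:
            study = simulate_study(SimulationConfig(
                seed=config.seed, fold_backend=config.fold_backend,
                **config.sim_params))
            write_study(study, sim_dir)
            _write_manifest(workdir, "simulate", stage_inputs, params,
                            [sim_dir / "genome.fasta", sim_dir / "srna_counts.tsv"])
            status["simulate"] = "done"

    analysis_inputs = [sim_dir / "genome.fasta", sim_dir / "srna_counts.tsv"]
    analysis_stages = [s for s in STAGE_ORDER[1:] if s in requested]
    if analysis_stages:
        if _can_skip(workdir, "analysis", analysis_inputs, params):
            status.update({s: "skipped" for s in analysis_stages})
            log.info("analysis stages reused from manifests")
        else:
            study = simulate_study(SimulationConfig(
                seed=config.seed, fold_backend=config.fold_backend,
                **config.sim_params))
            result = benchmark.run_pipeline(study, n_shuffles=config.n_shuffles,
                                            shuffle_seed=config.seed + 1,
                                            backend=config.fold_backend)
            _write_outputs(workdir, result)
            _write_manifest(workdir, "analysis", analysis_inputs, params,
                            [workdir / "summary.json"])
            status.update({s: "done" for s in analysis_stages})

    log.info("pipeline finished in %.1f s", time.time() - t0)
    return {"status": status, "workdir": str(workdir),
            "elapsed_s": round(time.time() - t0, 2)}


def _write_outputs(workdir: Path, result) -> None:
    result.tags.to_csv(workdir / "annotated_tags.tsv", sep="\t", index=False)
    result.known_records.to_csv(workdir / "known_mirnas.tsv", sep="\t", index=False)
    novel_rows = [{
        "name": c.name, "sequence": c.mature_sequence, "arm": c.arm,
        "energy": c.candidate.fold.energy, "copy_number": c.copy_number,
        "n_precursors": c.n_precursors, "has_star": c.has_star,
        "count_control": c.count_control, "count_cms": c.count_cms,
        "loci": ";".join(f"{ch}:{s}-{e}({st})" for ch, s, e, st in c.loci),
    } for c in result.novel_calls]
    pd.DataFrame(novel_rows).to_csv(workdir / "novel_mirnas.tsv", sep="\t",
                                    index=False)
    result.mirna_de.to_csv(workdir / "mirna_de.tsv", sep="\t", index=False)
    result.gene_de.to_csv(workdir / "gene_de.tsv", sep="\t", index=False)
    result.target_hits.to_csv(workdir / "target_hits.tsv", sep="\t", index=False)
    result.pairs.to_csv(workdir / "pairs.tsv", sep="\t", index=False)
    with open(workdir / "summary.json", "w") as fh:
        json.dump(result.summary, fh, indent=2, sort_keys=True)
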