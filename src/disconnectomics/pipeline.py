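"""End-to-end orchestration: simulate -> connectome -> disconnectome -> SVR -> report.

Every stage reads and writes plain files, so any later stage can be resumed
from disk without hidden state. One global seed fans out to per-stage seeds
through a declared derivation (SeedSequence over the stage name's bytes), so
individual stages are independently reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .behavior import read_records_csv, record_from_sheets, read_sheets_csv, write_records_csv
from .connectome import DEFAULT_MAX_ROIS, DEFAULT_RADIUS_MM
from .disconnectome import (
    CohortDisconnectomePipeline,
    LesionMask,
    assemble_features,
)
from .errors import ConfigurationError, DataContractError
from .network import DEFAULT_HUB_THRESHOLD, NetworkReport, make_report
from .parcellation import Parcellation
from .svr import ClsmResult, SvrConfig, optimize_C, permutation_test
from .synthetic import make_cohort, write_cohort
from .tractogram import load_tck


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed and stage name."""
    entropy = [global_seed] + list(stage.encode("utf-8"))
    return int(np.random.SeedSequence(entropy).generate_state(1)[0] % (2**31))


@dataclass
class PipelineConfig:
    """One config object drives both simulation and analysis.

    ``cohort`` holds keyword arguments of :func:`disconnectomics.make_cohort`
    (minus the seed, which derives from ``seed``); paths point at the on-disk
    artifacts the analysis consumes, normally those ``run_simulate`` wrote.
    """

    output_dir: str = "out"
    cohort_dir: str = "out/cohort"
    seed: int = 0
    radius_mm: float = DEFAULT_RADIUS_MM
    max_rois: int = DEFAULT_MAX_ROIS
    hub_threshold: int = DEFAULT_HUB_THRESHOLD
    cohort: dict = field(default_factory=dict)
    svr: SvrConfig = field(default_factory=SvrConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        svr_raw = raw.pop("svr", {})
        if "c_exponent_range" in svr_raw:
            svr_raw["c_exponent_range"] = tuple(svr_raw["c_exponent_range"])
        if "tradeoff_weights" in svr_raw:
            svr_raw["tradeoff_weights"] = tuple(svr_raw["tradeoff_weights"])
        try:
            return cls(**raw, svr=SvrConfig(**svr_raw))
        except TypeError as exc:
            raise ConfigurationError(f"bad pipeline config: {exc}") from exc

    def to_yaml(self, path: str | Path) -> None:
        raw = dataclasses.asdict(self)
        raw["svr"]["c_exponent_range"] = list(raw["svr"]["c_exponent_range"])
        raw["svr"]["tradeoff_weights"] = list(raw["svr"]["tradeoff_weights"])
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True)


def run_simulate(config: PipelineConfig) -> Path:
    """Generate a synthetic cohort and write all its artifacts; returns the manifest."""
    cohort = make_cohort(seed=stage_seed(config.seed, "simulate"), **config.cohort)
    return write_cohort(cohort, config.cohort_dir)


def run_coc(config: PipelineConfig, sheets_csv: str | Path, out_csv: str | Path) -> None:
    """Score raw cancellation sheets into behaviour records."""
    sheets = read_sheets_csv(sheets_csv)
    records = [record_from_sheets(pid, sh) for pid, sh in sorted(sheets.items())]
    write_records_csv(records, out_csv)


def _load_inputs(config: PipelineConfig):
    root = Path(config.cohort_dir)
    manifest_path = root / "manifest.json"
    if not manifest_path.exists():
        raise ConfigurationError(f"no cohort manifest at {manifest_path}")
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    parcellation = Parcellation.load(
        root / manifest["parcellation"], root / manifest["parcellation_labels"]
    )
    streamlines = load_tck(root / manifest["tractogram"])
    lesions = [LesionMask.load(root / rel, Path(rel).stem) for rel in manifest["lesions"]]
    behaviour = read_records_csv(root / manifest["behaviour"])
    return parcellation, streamlines, lesions, behaviour


def run_full(config: PipelineConfig) -> tuple[ClsmResult, NetworkReport]:
    """Execute the full analysis chain and write every intermediate artifact.

    connectome -> per-patient disconnectomes -> feature assembly ->
    C optimisation -> permutation test -> network report. Logs the chosen C,
    link counts and stage timings to ``pipeline.log`` (timings stay out of
    the CSV artifacts so reruns are byte-identical).
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(msg: str) -> None:
        log_lines.append(f"[{time.strftime('%H:%M:%S')}] {msg}")

    parcellation, streamlines, lesions, behaviour = _load_inputs(config)
    if len(lesions) != len(behaviour):
        raise DataContractError("lesion and behaviour counts differ")
    t0 = time.time()
    pipe = CohortDisconnectomePipeline(
        parcellation, streamlines, radius_mm=config.radius_mm, max_rois=config.max_rois
    )
    pipe.normative.save_csv(out / "normative_connectome.csv", parcellation.names)
    log(f"connectome: {pipe.normative.total()} counted streamlines "
        f"({time.time() - t0:.1f}s)")

    t0 = time.time()
    disconnectomes = pipe.cohort_disconnectomes(lesions)
    long_rows = []
    for lesion, d in zip(lesions, disconnectomes):
        iu, ju = np.triu_indices(len(d.roi_order), k=1)
        nz = d.counts[iu, ju] > 0
        for i, j in zip(iu[nz], ju[nz]):
            long_rows.append(
                {
                    "patient_id": lesion.patient_id,
                    "roi_a": d.roi_order[i],
                    "roi_b": d.roi_order[j],
                    "disconnected": int(d.counts[i, j]),
                }
            )
    pd.DataFrame(
        long_rows, columns=["patient_id", "roi_a", "roi_b", "disconnected"]
    ).to_csv(out / "disconnectomes.csv", index=False)
    log(f"disconnectomes: {len(lesions)} patients ({time.time() - t0:.1f}s)")

    features = assemble_features(
        disconnectomes,
        parcellation.hemisphere,
        patient_ids=[l.patient_id for l in lesions],
    )
    features.to_dataframe(parcellation.names).to_csv(out / "features.csv")
    y = np.array([r.coc_compound for r in behaviour])
    log(f"features: {features.n_links} retained links, {len(y)} patients")

    svr_config = dataclasses.replace(config.svr, seed=stage_seed(config.seed, "svr"))
    t0 = time.time()
    cv = optimize_C(features.matrix, y, svr_config)
    cv.save_csv(out / "cv_results.csv")
    log(f"optimize_C: chosen C = {cv.chosen_C:g} ({time.time() - t0:.1f}s)")

    t0 = time.time()
    result = permutation_test(
        features.matrix, y, cv.chosen_C, svr_config, link_index=features.link_index
    )
    result.save_csv(out / "clsm_results.csv", parcellation.names)
    log(
        f"permutation_test: {int(result.significant.sum())} significant links "
        f"of {result.n_links} ({time.time() - t0:.1f}s)"
    )

    report = make_report(result, parcellation, hub_threshold=config.hub_threshold)
    report.save(out / "report", parcellation)
    run_manifest = {
        "version": __version__,
        "seed": config.seed,
        "chosen_C": cv.chosen_C,
        "n_links": features.n_links,
        "n_significant": int(result.significant.sum()),
        "config": {
            "radius_mm": config.radius_mm,
            "max_rois": config.max_rois,
            "hub_threshold": config.hub_threshold,
            "svr": {**dataclasses.asdict(svr_config),
                    "c_exponent_range": list(svr_config.c_exponent_range),
                    "tradeoff_weights": list(svr_config.tradeoff_weights)},
        },
    }
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(run_manifest, fh, indent=2, sort_keys=True)
    with open(out / "pipeline.log", "w") as fh:
        fh.write("\n".join(log_lines) + "\n")
    return result, report
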