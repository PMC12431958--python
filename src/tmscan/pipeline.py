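"""End-to-end pipeline driver: simulate -> forward -> reconstruct -> segment -> analyze."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as tio
from .config import RunConfig, config_to_dict
from .forward import build_array, enumerate_paths
from .phantom import SubjectScans, generate_cohort
from .recon import reconstruct_phantom
from .segment import segment_scan
from .stats import SubjectRecord, StatResult, breast_average, cohort_report

logger = logging.getLogger(__name__)


@dataclass
class RunManifest:
    config_hash: str
    files: dict[str, list[str]] = field(default_factory=dict)
    started: str = ""
    finished: str = ""

    def add(self, stage: str, path: Path) -> None:
        self.files.setdefault(stage, []).append(str(path))


def _config_hash(cfg: RunConfig) -> str:
    payload = json.dumps(config_to_dict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _stat_to_json(obj):
    if isinstance(obj, StatResult):
        return dataclasses.asdict(obj)
    if isinstance(obj, dict):
        return {k: _stat_to_json(v) for k, v in obj.items()}
    return obj


def analyze_subject(
    subject: SubjectScans,
    cfg: RunConfig,
    pairs,
    recon_seed: int,
) -> tuple[SubjectRecord, dict]:
    """Reconstruct and segment the requested views of one subject."""
    rng = np.random.default_rng(recon_seed)
    view_seeds = {v: int(s) for v, s in zip(sorted(subject.phantoms), rng.integers(0, 2**31 - 1, size=len(subject.phantoms)))}
    eps_avg, separations, areas, images, segs = {}, {}, {}, {}, {}
    for view in cfg.views:
        phantom = subject.phantoms[view]
        image = reconstruct_phantom(
            phantom,
            pairs=pairs,
            sweep=cfg.sweep,
            snr_db=cfg.snr_db,
            seed=view_seeds[view],
            params=cfg.transform,
            footprint_radius_mm=cfg.footprint_radius_mm,
        )
        image.view = view
        image.subject_id = subject.subject_id
        seg = segment_scan(image, cfg.segmentation)
        eps_avg[view] = breast_average(image, seg.breast_mask)
        separations[view] = phantom.separation_mm
        areas[view] = seg.breast_area_ratio
        images[view] = image
        segs[view] = seg
    record = SubjectRecord(
        subject_id=subject.subject_id,
        group=subject.group,
        eps_avg=eps_avg,
        separation_mm=separations,
        area_ratio=areas,
    )
    return record, {"images": images, "segmentations": segs}


def run_cohort(cfg: RunConfig) -> tuple[list[SubjectScans], list[SubjectRecord]]:
    """Simulate, reconstruct and segment a cohort in memory.

    Returns the generated subjects (with ground truth) and the per-subject
    records recovered by the measurement chain; used by :func:`run_pipeline`
    and by analysis scripts that do not need files on disk.
    """
    cohort_spec = dataclasses.replace(cfg.cohort, master_seed=cfg.master_seed, grid=cfg.grid)
    subjects = generate_cohort(cohort_spec)
    geom = build_array(cfg.grid, d_mm=60.0, pairing_radius_mm=cfg.pairing_radius_mm)
    pairs = enumerate_paths(geom)
    seed_rng = np.random.default_rng(np.random.SeedSequence([cfg.master_seed, 0xC0DE]))
    recon_seeds = seed_rng.integers(0, 2**31 - 1, size=max(1, len(subjects)))
    records = []
    for i, subject in enumerate(subjects):
        record, _ = analyze_subject(subject, cfg, pairs, int(recon_seeds[i]))
        records.append(record)
    return subjects, records


def run_pipeline(cfg: RunConfig) -> RunManifest:
    """Run every stage on a synthetic cohort; outputs land under cfg.out_dir.

    Fully deterministic given the master seed: re-running the same config
    produces byte-identical CSV tables.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=_config_hash(cfg), started=time.strftime("%Y-%m-%dT%H:%M:%S"))

    logger.info("stage=simulate-cohort n_healthy=%d n_cancer=%d", cfg.cohort.n_healthy, cfg.cohort.n_cancer)
    cohort_spec = dataclasses.replace(cfg.cohort, master_seed=cfg.master_seed, grid=cfg.grid)
    subjects = generate_cohort(cohort_spec)

    geom = build_array(cfg.grid, d_mm=60.0, pairing_radius_mm=cfg.pairing_radius_mm)
    pairs = enumerate_paths(geom)
    logger.info("stage=forward n_paths=%d", len(pairs))

    seed_rng = np.random.default_rng(np.random.SeedSequence([cfg.master_seed, 0xC0DE]))
    recon_seeds = seed_rng.integers(0, 2**31 - 1, size=max(1, len(subjects)))

    records = []
    for i, subject in enumerate(subjects):
        try:
            record, artifacts = analyze_subject(subject, cfg, pairs, int(recon_seeds[i]))
        except Exception as exc:  # pragma: no cover - defensive
            raise RuntimeError(
                f"pipeline failed at subject={subject.subject_id}: {exc}"
            ) from exc
        records.append(record)
        logger.info("stage=reconstruct subject=%s done", subject.subject_id)
        if cfg.save_phantoms:
            for view, phantom in subject.phantoms.items():
                p = out / "phantoms" / f"{subject.subject_id}_{view}.csv"
                p.parent.mkdir(exist_ok=True)
                tio.write_phantom(p, phantom)
                manifest.add("phantoms", p)
        if cfg.save_images:
            for view, image in artifacts["images"].items():
                p = out / "images" / f"{subject.subject_id}_{view}.csv"
                p.parent.mkdir(exist_ok=True)
                tio.write_image(p, image)
                manifest.add("images", p)
            for view, seg in artifacts["segmentations"].items():
                p = out / "segmentations" / f"{subject.subject_id}_{view}.json"
                p.parent.mkdir(exist_ok=True)
                tio.write_segmentation(p, seg)
                manifest.add("segmentations", p)

    logger.info("stage=analyze n_subjects=%d", len(records))
    report = cohort_report(records)
    stats_dir = out / "stats"
    stats_dir.mkdir(exist_ok=True)
    for name in ("subjects", "ratios", "group_mean_ratios"):
        p = stats_dir / f"{name}.csv"
        report[name].to_csv(p, index=False, float_format="%.12g")
        manifest.add("stats", p)
    p = stats_dir / "tests.json"
    p.write_text(json.dumps(_stat_to_json(report["tests"]), indent=1, sort_keys=True))
    manifest.add("stats", p)

    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(dataclasses.asdict(manifest), indent=1))
    missing = [f for fs in manifest.files.values() for f in fs if not Path(f).exists()]
    if missing:
        raise RuntimeError(f"manifest lists missing files: {missing[:3]}")
    return manifest
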