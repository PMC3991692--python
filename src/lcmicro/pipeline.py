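"""End-to-end pipeline: single-scan analysis and the in-silico repeatability experiment.

``run_single_scan`` chains denoise -> analyzable-LC mask -> local-threshold
segmentation -> morphometry for one volume.  ``run_repro_experiment`` is the
in-silico analogue of a clinical repeatability study: a cohort of phantom
eyes, each "scanned" twice (the second scan via a rigid perturbation,
contrast change and fresh speckle), run through the full pipeline, and
summarized with the nested measurement error model into a table of mean,
imprecision SD and relative imprecision per parameter.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as lcio
from .imprecision import fit_measurement_error_model
from .morphometry import compute_params
from .phantom import (
    Phantom,
    PhantomSpec,
    RepeatScanSpec,
    generate_phantom,
    simulate_repeat_scan,
)
from .segmentation import (
    SegConfig,
    denoise,
    estimate_relative_noise,
    find_analyzable_region,
    segment,
)
from .types import LCParams, Segmentation, Volume

__all__ = [
    "PipelineConfig",
    "boundary_smooth_radius",
    "StatsConfig",
    "ExperimentConfig",
    "analyze_volume",
    "run_single_scan",
    "run_repro_experiment",
    "eye_seed",
]

log = logging.getLogger("lcmicro")


@dataclass(frozen=True)
class StatsConfig:
    bootstrap_draws: int = 1000
    seed: int = 0

    def to_dict(self) -> dict:
        return {"bootstrap_draws": self.bootstrap_draws, "seed": self.seed}

    @classmethod
    def from_dict(cls, d: dict) -> "StatsConfig":
        _reject_unknown(cls, d)
        return cls(**d)


@dataclass(frozen=True)
class ExperimentConfig:
    """Cohort design of the in-silico repeatability experiment."""

    n_eyes: int = 12
    master_seed: int = 0
    #: per-eye relative jitter of the true pore/beam targets (biological
    #: between-eye variation); 0 makes all eyes identical in expectation
    target_jitter: float = 0.08

    def to_dict(self) -> dict:
        return {
            "n_eyes": self.n_eyes,
            "master_seed": self.master_seed,
            "target_jitter": self.target_jitter,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        _reject_unknown(cls, d)
        return cls(**d)


def _reject_unknown(cls, d: dict) -> None:
    unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")


@dataclass(frozen=True)
class PipelineConfig:
    """Single JSON-serializable document configuring every stage."""

    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    seg: SegConfig = field(default_factory=SegConfig)
    repeat: RepeatScanSpec = field(default_factory=RepeatScanSpec)
    stats: StatsConfig = field(default_factory=StatsConfig)
    experiment: ExperimentConfig = field(default_factory=ExperimentConfig)

    def to_dict(self) -> dict:
        return {
            "phantom": self.phantom.to_dict(),
            "seg": self.seg.to_dict(),
            "repeat": self.repeat.to_dict(),
            "stats": self.stats.to_dict(),
            "experiment": self.experiment.to_dict(),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        unknown = set(d) - {"phantom", "seg", "repeat", "stats", "experiment"}
        if unknown:
            raise ValueError(f"unknown PipelineConfig keys: {sorted(unknown)}")
        return cls(
            phantom=PhantomSpec.from_dict(d.get("phantom", {})),
            seg=SegConfig.from_dict(d.get("seg", {})),
            repeat=RepeatScanSpec.from_dict(d.get("repeat", {})),
            stats=StatsConfig.from_dict(d.get("stats", {})),
            experiment=ExperimentConfig.from_dict(d.get("experiment", {})),
        )

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        return cls.from_dict(json.loads(text))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


def eye_seed(master_seed: int, eye_index: int, replicate: int) -> int:
    """Stable per-eye, per-replicate sub-seed (< 2**31).

    Counter-style fan-out: adding eyes to a cohort never perturbs the data
    of earlier eyes, and replicates of one eye get independent streams.
    """
    ss = np.random.SeedSequence([int(master_seed), int(eye_index), int(replicate)])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def boundary_smooth_radius(rel_noise: float) -> float:
    """Morphometry interface-regularization radius (um) for a noise level.

    Proportional to the measured relative noise and capped; exactly zero
    for clean volumes so noise-free segmentations are measured as-is.
    """
    return min(52.0 * rel_noise, 12.0) if rel_noise > 0.02 else 0.0


def analyze_volume(volume: Volume, cfg: SegConfig) -> tuple[LCParams, Segmentation]:
    """Denoise, mask, segment and measure one volume.

    The returned segmentation is the classifier output.  The parameters are
    measured with a boundary regularization whose radius is scaled from the
    raw volume's measured relative noise (zero on clean volumes), because
    sphere-fitting morphometry amplifies the interface roughness that
    speckle leaves in any voxel-wise classification.
    """
    t0 = time.perf_counter()
    rel_noise = estimate_relative_noise(volume)
    den = denoise(volume, cfg)
    mask = find_analyzable_region(den, cfg)
    seg = segment(den, mask, cfg)
    params = compute_params(seg, boundary_smooth=boundary_smooth_radius(rel_noise))
    log.info("analyze_volume: %.2fs", time.perf_counter() - t0)
    return params, seg


def run_single_scan(
    volume_path: str | Path,
    config: PipelineConfig,
    out_dir: str | Path | None = None,
) -> LCParams:
    """Full pipeline on one stored scan; optionally write all stage outputs.

    Reads the TIFF stack and its JSON sidecar (the sidecar supplies voxel
    spacing; a missing sidecar is an explicit error telling the caller to
    provide spacing).  Writes params CSV, the labeled segmentation stack and
    a run log with the config hash when ``out_dir`` is given.
    """
    volume = lcio.read_volume(volume_path)
    try:
        params, seg = analyze_volume(volume, config.seg)
    except ValueError as exc:
        raise RuntimeError(f"segmentation/morphometry stage failed: {exc}") from exc
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        lcio.write_params_csv(out / "params.csv", params, ids=[Path(volume_path).stem])
        smooth_um = boundary_smooth_radius(estimate_relative_noise(volume))
        lcio.write_segmentation(
            out / "segmentation.tif", seg, extra_meta={"boundary_smooth_um": smooth_um}
        )
        (out / "run.json").write_text(
            json.dumps(
                {"config_hash": config.config_hash(), "config": config.to_dict()},
                indent=2,
            )
        )
    return params


def _perturbed_spec(base: PhantomSpec, rng: np.random.Generator, jitter: float) -> PhantomSpec:
    if jitter == 0:
        return base
    f1, f2 = rng.uniform(1 - jitter, 1 + jitter, size=2)
    return dataclasses.replace(
        base,
        true_pore_diameter_mean=base.true_pore_diameter_mean * f1,
        true_beam_thickness_mean=base.true_beam_thickness_mean * f2,
    )


def simulate_cohort_scan_pair(
    config: PipelineConfig, eye_index: int
) -> tuple[Phantom, Phantom]:
    """One phantom eye and its simulated second acquisition."""
    seed1 = eye_seed(config.experiment.master_seed, eye_index, 1)
    seed2 = eye_seed(config.experiment.master_seed, eye_index, 2)
    rng = np.random.default_rng(eye_seed(config.experiment.master_seed, eye_index, 0))
    spec = dataclasses.replace(
        _perturbed_spec(config.phantom, rng, config.experiment.target_jitter),
        seed=seed1,
    )
    eye = generate_phantom(spec)
    rs = config.repeat
    if rs.fresh_speckle:
        rs = dataclasses.replace(rs, new_speckle_seed=seed2)
    scan2 = simulate_repeat_scan(eye, rs)
    return eye, scan2


def run_repro_experiment(
    config: PipelineConfig,
    out_dir: str | Path | None = None,
) -> pd.DataFrame:
    """In-silico repeatability study over a cohort of phantom eyes.

    Returns a table with one row per parameter: cohort mean (SD), fitted
    imprecision SD and relative imprecision (percent).  Each phantom eye is
    one subject (single group); the long-format measurement table is also
    written when ``out_dir`` is given.  Deterministic in the master seed.
    """
    rows = []
    for i in range(config.experiment.n_eyes):
        t0 = time.perf_counter()
        eye, scan2 = simulate_cohort_scan_pair(config, i)
        for rep, ph in ((1, eye), (2, scan2)):
            params, _ = analyze_volume(ph.volume, config.seg)
            for name in LCParams.REPEATABILITY_PARAMS:
                rows.append(
                    {
                        "subject_id": f"P{i:03d}",
                        "eye_id": f"P{i:03d}-OD",
                        "group": "phantom",
                        "replicate": rep,
                        "parameter": name,
                        "value": getattr(params, name),
                    }
                )
        log.info("eye %d: %.1fs", i, time.perf_counter() - t0)
    table = pd.DataFrame(rows)

    report_rows = []
    for name in LCParams.REPEATABILITY_PARAMS:
        est = fit_measurement_error_model(table, name)
        report_rows.append(
            {
                "parameter": name,
                "mean": est.mean_value,
                "between_eye_sd": float(
                    np.sqrt(est.subject_var + est.eye_within_subject_var)
                ),
                "imprecision_sd": est.imprecision_sd,
                "relative_imprecision_pct": est.relative_imprecision,
                "n_eyes": est.n_eyes,
            }
        )
    report = pd.DataFrame(report_rows)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        lcio.write_repeated_table(out / "measurements.csv", table)
        report.to_csv(out / "imprecision_report.csv", index=False)
        (out / "run.json").write_text(
            json.dumps(
                {"config_hash": config.config_hash(), "config": config.to_dict()},
                indent=2,
            )
        )
    return report
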