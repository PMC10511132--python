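"""Pipeline configuration and the end-to-end demo runner.

The configuration carries the analysis thresholds used throughout the
pipeline — the 5x background-SD cluster rule, the [50, 3000] cell
count retention window, the 30% clone-assignment threshold, and the
RGB channel scaling factors — plus seeds and problem sizes for the
synthetic stages.  It round-trips losslessly through YAML.
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
import yaml

logger = logging.getLogger("exmpipe")


@dataclass
class PipelineConfig:
    seed: int = 0
    # analysis thresholds (defaults are the pipeline's standard values)
    cluster_sd_multiple: float = 5.0
    cell_count_window: tuple = (50, 3000)
    clone_threshold: float = 0.30
    channel_scaling: dict = field(
        default_factory=lambda: {
            "dna_repair": 3.33,
            "proliferation": 3.33,
            "emt": 2.5,
        }
    )
    spot_threshold_sd: float = 5.0
    k_peaks: int = 3
    codebook_path: str = ""
    # demo problem sizes
    expansion_factor: float = 4.2
    distortion_amp_um: float = 0.5
    qc_field_px: int = 96
    qc_register: bool = True
    n_cells_fish: int = 15
    spots_per_cell: float = 30.0
    n_profiles: int = 20
    n_amplicons: int = 150
    n_cells_counts: int = 1000
    verbosity: int = 1

    def to_yaml(self, path=None) -> str:
        payload = dataclasses.asdict(self)
        payload["cell_count_window"] = list(self.cell_count_window)
        text = yaml.safe_dump(payload, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "PipelineConfig":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = yaml.safe_load(text)
        if "cell_count_window" in payload:
            payload["cell_count_window"] = tuple(payload["cell_count_window"])
        return cls(**payload)

    def digest(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def _write_report(out_dir: Path, stage: str, payload: dict) -> None:
    (out_dir / f"{stage}_report.json").write_text(
        json.dumps(payload, indent=1, default=float)
    )


def run_pipeline(config: PipelineConfig, out_dir) -> Path:
    """Run every stage on seeded synthetic data and write stage reports.

    Executes simulate -> qc -> spots -> periodicity -> exseq -> clones
    at demo problem sizes, writing one JSON report per stage plus a
    provenance record (config hash, seed, package version).  Any stage
    failure propagates with the stage named.
    """
    from . import __version__, clones, exseq, periodicity, qc, spots, synthetic

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config.seed)
    stages = {
        "qc": _stage_qc,
        "spots": _stage_spots,
        "periodicity": _stage_periodicity,
        "exseq": _stage_exseq,
        "clones": _stage_clones,
    }
    provenance = dict(
        config_hash=config.digest(), seed=seed, version=__version__
    )
    (out_dir / "provenance.json").write_text(json.dumps(provenance, indent=1))
    config.to_yaml(out_dir / "config.yaml")
    for name, fn in stages.items():
        t0 = time.time()
        try:
            report = fn(config, seed)
        except Exception as exc:
            raise RuntimeError(f"stage '{name}' failed: {exc}") from exc
        report["elapsed_s"] = round(time.time() - t0, 2)
        _write_report(out_dir, name, report)
        logger.info("stage %s done in %.1fs", name, report["elapsed_s"])
    return out_dir


def _stage_qc(config, seed):
    from . import qc, synthetic

    pre, seg, truth = synthetic.gen_cell_images(
        4, config.qc_field_px, seed=seed, radius_range=(7.0, 10.0)
    )
    post, true_field, _ = synthetic.gen_expansion_pair(
        pre,
        config.expansion_factor,
        distortion_amp=config.distortion_amp_um,
        smoothness=5.0,
        seed=seed + 1,
    )
    geom = qc.measure_regions(seg)
    pairs = np.stack(
        [
            geom["major_axis"].to_numpy(),
            geom["major_axis"].to_numpy() * config.expansion_factor,
        ],
        axis=1,
    )
    ef = qc.expansion_factor(pairs)
    lengths = [2.0, 5.0, 10.0]
    curve = qc.rms_length_error(true_field, lengths, n_pairs=300, seed=seed)
    report = dict(
        expansion_factor=ef.factor,
        expansion_factor_sd=ef.sd,
        rms_error_um=dict(zip(map(str, lengths), curve.rms_error)),
        true_field_rms_um=true_field.rms(),
    )
    if config.qc_register:
        scaled = qc.scale_to_reference(
            pre, config.expansion_factor, post.data.shape
        )
        est, score = qc.register_nonrigid(
            post, scaled, grid_spacing=6.0, levels=2, iterations=40
        )
        report["registered_field_rms_um"] = est.rms(margin=0.1)
        report["registration_similarity"] = score
    return report


def _stage_spots(config, seed):
    from . import spots, synthetic

    _, seg, _ = synthetic.gen_cell_images(config.n_cells_fish, 256, seed=seed)
    img, truth = synthetic.gen_fish_spots(
        seg, config.spots_per_cell, psf_sigma=1.5, noise_sd=0.02, seed=seed + 1
    )
    detected = spots.detect_spots(img, 1.5, config.spot_threshold_sd)
    detected = spots.assign_spots_to_cells(detected, seg)
    counts = spots.counts_per_cell(detected, seg)
    rng = np.random.default_rng(seed + 2)
    before = counts.to_numpy()
    after = rng.binomial(before, 0.98)
    reg = spots.retention_regression(np.stack([before, after], axis=1))
    return dict(
        n_spots=len(detected),
        n_true=len(truth.truth_tables["spots"]),
        retention_slope=reg.slope,
        retention_r_squared=reg.r_squared,
    )


def _stage_periodicity(config, seed):
    from . import periodicity, synthetic

    means = []
    for i in range(config.n_profiles):
        profile, _ = synthetic.gen_axon_profile(
            period_nm=190.0, n_rings=15, noise_sd=0.1, seed=seed + i
        )
        rescaled = periodicity.rescale_profile(profile)
        clusters = periodicity.detect_clusters(rescaled, config.cluster_sd_multiple)
        if not periodicity.select_segments(len(clusters)):
            continue
        result = periodicity.estimate_period(rescaled, k_peaks=config.k_peaks)
        if not result.insufficient:
            means.append(result.mean_periodicity)
    return dict(
        n_profiles=config.n_profiles,
        n_eligible=len(means),
        mean_periodicity_nm=float(np.mean(means)),
        sd_periodicity_nm=float(np.std(means)),
    )


def _stage_exseq(config, seed):
    from . import exseq, synthetic

    codebook = synthetic.default_codebook()
    crosstalk = np.full((4, 4), 0.05) + np.eye(4) * 0.85
    stacks, seg, truth = synthetic.gen_exseq_stacks(
        codebook,
        n_amplicons=config.n_amplicons,
        crosstalk=crosstalk,
        base_error_rate=0.05,
        drift_px=1.5,
        seed=seed,
        noise_sd=5.0,
    )
    reads, matrix = exseq.decode_stacks(
        stacks, codebook, seg=seg, crosstalk=crosstalk
    )
    matched = reads["status"].eq("matched")
    return dict(
        n_puncta=len(reads),
        n_true=len(truth.truth_tables["reads"]),
        matched_fraction=float(matched.mean()),
        total_counts=int(matrix.to_numpy().sum()),
    )


def _stage_clones(config, seed):
    from . import clones, synthetic

    matrix, truth = synthetic.gen_count_matrix(
        config.n_cells_counts, mean_counts=500.0, seed=seed
    )
    lo, hi = config.cell_count_window
    filtered, report = clones.filter_cells(matrix, lo, hi)
    normalized = clones.normalize(filtered)
    pos, neg, info = clones.pca_gene_groups(normalized)
    supervised = clones.assign_clones(
        filtered,
        truth.truth_tables["markers_a"],
        truth.truth_tables["markers_b"],
        threshold=config.clone_threshold,
    )
    unsupervised = clones.assign_clones(
        filtered, pos, neg, threshold=config.clone_threshold,
        labels=("pca_pos", "pca_neg"),
    )
    agree = clones.cross_method_agreement(
        supervised["clone_label"],
        unsupervised["clone_label"],
        sample_n=min(2000, len(filtered)),
        seed=seed,
    )
    return dict(
        retained=report["retained"],
        removed=report["removed"],
        pca_variance_ratio=info["variance_ratio"],
        agreement_1_to_2=agree["agreement_1_to_2"],
        agreement_2_to_1=agree["agreement_2_to_1"],
    )
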