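"""End-to-end pipeline: SAM → midpoints → binned tracks → smoothing →
peaks → site profiles → clustering and the cross-condition t-test, driven
by a single validated configuration with explicit seeds.

Every stage output is written under the run directory and recorded in a
manifest with parameter values and content checksums, so two runs with the
same config are verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from pathlib import Path
from typing import Optional

from pydantic import BaseModel, Field, field_validator

import nucparticle
from nucparticle import cluster_stats, peakcall, site_profile, smoothing, track
from nucparticle.sam_ingest import SizeClassSpec, read_sam, stratify

logger = logging.getLogger(__name__)


class PipelineStageError(RuntimeError):
    """A stage failed; carries the stage name and the partial manifest."""

    def __init__(self, stage: str, manifest: dict, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.manifest = manifest


class RunConfig(BaseModel):
    """All global parameters of one two-condition run."""

    sam_paths: dict[str, str]  # condition label -> SAM path
    features_path: str
    out_dir: str
    seed: int
    peak_threshold: float  # no default: must be stated explicitly per run
    size_class_bp: int = 150
    size_tolerance: float = 0.2
    bin_width: int = 10
    kde_bandwidth: float = 30.0
    profile_half_width: int = 1200
    cluster_window: tuple[int, int] = (0, 1500)
    cluster_on: Optional[str] = None  # condition whose matrix is clustered
    k: int = 9
    subset_size: int = 100
    n_subsets: int = 29
    ttest_offsets_bp: list[int] = Field(default_factory=lambda: [522])

    @field_validator("sam_paths")
    @classmethod
    def _at_least_one_condition(cls, v: dict[str, str]) -> dict[str, str]:
        if not v:
            raise ValueError("sam_paths must name at least one condition")
        return v

    @field_validator("bin_width", "size_class_bp", "profile_half_width", "k",
                     "subset_size", "n_subsets")
    @classmethod
    def _positive(cls, v: int) -> int:
        if v <= 0:
            raise ValueError("must be positive")
        return v


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage; return (and write) the run manifest.

    Per condition: midpoints → raw.sgr → ma3.sgr + kde.sgr → peaks.tsv →
    profile.tsv + matrix.tsv.  Across conditions: cluster one condition's
    matrix, re-order the others by its cluster order, and run the
    subsampled t-test at the configured offsets.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": nucparticle.__version__,
        "python": platform.python_version(),
        "config": json.loads(config.model_dump_json()),
        "files": {},
        "stats": {},
    }

    def record(key: str, path: Path) -> None:
        manifest["files"][key] = {"path": str(path), "sha256": _sha256(path)}

    spec = SizeClassSpec(
        nominal_bp=config.size_class_bp, tolerance_fraction=config.size_tolerance
    )
    features = site_profile.read_features(config.features_path)
    kde_spec = smoothing.KernelSpec(bandwidth=config.kde_bandwidth)

    matrices: dict[str, site_profile.ProfileMatrix] = {}
    stage = "setup"
    try:
        for cond, sam_path in config.sam_paths.items():
            cdir = out_dir / cond
            cdir.mkdir(exist_ok=True)

            stage = f"{cond}:ingest"
            sam = read_sam(sam_path)
            midpoints = stratify(sam.records, spec)
            manifest["stats"][f"{cond}.n_pairs"] = len(sam.records)
            manifest["stats"][f"{cond}.n_midpoints"] = len(midpoints)

            stage = f"{cond}:histogram"
            raw = track.build_histogram(midpoints, sam.chrom_lengths, config.bin_width)
            track.write_sgr(raw, cdir / "raw.sgr")
            record(f"{cond}.raw_sgr", cdir / "raw.sgr")

            stage = f"{cond}:smoothing"
            ma3 = smoothing.smooth_tracks(raw, "ma3")
            kde = smoothing.smooth_tracks(raw, "epanechnikov", kde_spec)
            track.write_sgr(ma3, cdir / "ma3.sgr")
            track.write_sgr(kde, cdir / "kde.sgr")
            record(f"{cond}.ma3_sgr", cdir / "ma3.sgr")
            record(f"{cond}.kde_sgr", cdir / "kde.sgr")

            stage = f"{cond}:peaks"
            peaks = peakcall.mark_peaks_genome(ma3, threshold=config.peak_threshold)
            peakcall.write_peaks(peaks, cdir / "peaks.tsv")
            record(f"{cond}.peaks_tsv", cdir / "peaks.tsv")
            total, per_chrom = peakcall.count_peaks(peaks)
            manifest["stats"][f"{cond}.n_peaks"] = total
            manifest["stats"][f"{cond}.n_peaks_per_chrom"] = per_chrom

            stage = f"{cond}:profile"
            profile = site_profile.cumulative_profile(
                kde, features, config.profile_half_width
            )
            site_profile.write_profile(profile, cdir / "profile.tsv")
            record(f"{cond}.profile_tsv", cdir / "profile.tsv")

            matrix = site_profile.profile_matrix(kde, features, config.cluster_window)
            matrix.to_tsv(cdir / "matrix.tsv")
            record(f"{cond}.matrix_tsv", cdir / "matrix.tsv")
            matrices[cond] = matrix

        conditions = list(config.sam_paths)
        if len(conditions) >= 2:
            stage = "cluster"
            cluster_on = config.cluster_on or conditions[-1]
            if cluster_on not in matrices:
                raise ValueError(f"cluster_on={cluster_on!r} is not a configured condition")
            result = cluster_stats.kmeans_profiles(
                matrices[cluster_on], k=config.k, seed=config.seed
            )
            cluster_stats.write_assignments(result, out_dir / "cluster_assignments.tsv")
            record("cluster_assignments", out_dir / "cluster_assignments.tsv")
            for cond in conditions:
                ordered = cluster_stats.apply_cluster_order(result, matrices[cond])
                path = out_dir / f"matrix_{cond}_ordered.tsv"
                ordered.to_tsv(path)
                record(f"{cond}.matrix_ordered", path)

            stage = "ttest"
            cond_a, cond_b = conditions[0], conditions[1]
            tt_report = {}
            for offset in config.ttest_offsets_bp:
                tt = cluster_stats.subsample_ttest(
                    matrices[cond_a].column_at(offset),
                    matrices[cond_b].column_at(offset),
                    subset_size=config.subset_size,
                    n_subsets=config.n_subsets,
                    seed=config.seed,
                    offset_bp=offset,
                )
                tt_report[str(offset)] = {
                    "t": tt.t_stat,
                    "p_two_tailed": tt.p_two_tailed,
                    "subset_size": tt.subset_size,
                    "n_subsets": tt.n_subsets,
                    "with_replacement": tt.with_replacement,
                }
            with open(out_dir / "ttest.json", "wt", encoding="utf-8") as fh:
                json.dump(tt_report, fh, indent=2)
            record("ttest_json", out_dir / "ttest.json")
            manifest["stats"]["ttest"] = tt_report
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        raise PipelineStageError(stage, manifest, exc) from exc

    stage = "manifest"
    with open(out_dir / "manifest.json", "wt", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
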