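"""End-to-end orchestration: filter → segment → match → register → mesh → measure.

`run_pipeline` wires the stages in flowchart order for one or more scans of
the same subject: each scan is filtered and segmented; the target cluster is
(optionally) verified against a feature library; with several scans, the later
ones are ICP-registered onto the first; the merged cloud is re-voxelised,
MLS-smoothed and meshed; finally the five body dimensions are measured from
landmark picks against the fitted ground plane and corrected for photographic
distance.  Every stage logs its point counts, and all stochastic stages are
seeded from the single pipeline seed.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .core_io import PointCloud, apply_transform, write_cloud
from .features import FeatureLibrary, MatchResult, NormalParams, estimate_normals, match_cluster
from .filters import FilterParams, fused_filter, voxel_grid_filter
from .measurement import (
    BodyDimensions,
    BodyPicks,
    CorrectionModel,
    DeviationReport,
    compute_body_dimensions,
    deviation_report,
)
from .registration import IcpParams, icp
from .segmentation import ClusterParams, PlaneModel, RansacParams, segment_target
from .surface import GptParams, MlsParams, TriangleMesh, greedy_projection_triangulate, mesh_quality, mls_resample

logger = logging.getLogger("bovimetry")

__all__ = ["PipelineConfig", "PipelineResult", "UnmatchedTargetError", "run_pipeline"]


class UnmatchedTargetError(RuntimeError):
    """The segmented cluster did not match the feature library."""


_BLOCKS = {
    "filter": FilterParams,
    "cluster": ClusterParams,
    "ransac": RansacParams,
    "normals": NormalParams,
    "icp": IcpParams,
    "mls": MlsParams,
    "gpt": GptParams,
}


@dataclass
class PipelineConfig:
    """All stage parameter blocks plus global reproducibility controls."""

    filter: FilterParams = field(default_factory=FilterParams)
    cluster: ClusterParams = field(default_factory=ClusterParams)
    ransac: RansacParams = field(default_factory=RansacParams)
    normals: NormalParams = field(default_factory=NormalParams)
    icp: IcpParams = field(default_factory=IcpParams)
    mls: MlsParams = field(default_factory=MlsParams)
    gpt: GptParams = field(default_factory=GptParams)
    seed: int = 0
    match_threshold: float | None = None

    def __post_init__(self) -> None:
        if self.ransac.seed is None:
            self.ransac = dataclasses.replace(self.ransac, seed=self.seed)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = set(_BLOCKS) | {"seed", "match_threshold"}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {}
        for name, block_cls in _BLOCKS.items():
            if name in raw:
                block = raw[name]
                valid = {f.name for f in dataclasses.fields(block_cls)}
                bad = set(block) - valid
                if bad:
                    raise ValueError(f"unknown keys in config block {name!r}: {sorted(bad)}")
                for key in ("x_range", "z_range", "viewpoint"):
                    if key in block:
                        block[key] = tuple(block[key]) if key != "viewpoint" else block[key]
                kwargs[name] = block_cls(**block)
        for key in ("seed", "match_threshold"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)


@dataclass
class PipelineResult:
    target: PointCloud
    plane: PlaneModel
    mesh: TriangleMesh
    dimensions: BodyDimensions | None
    report: DeviationReport | None
    match: MatchResult | None
    stage_counts: dict[str, int]
    photographic_distance: float

    @property
    def mesh_stats(self) -> dict:
        return mesh_quality(self.mesh)


def run_pipeline(
    scans: list[PointCloud],
    config: PipelineConfig | None = None,
    picks: dict[str, np.ndarray] | None = None,
    library: FeatureLibrary | None = None,
    correction: CorrectionModel | None = None,
    manual: dict[str, float] | None = None,
    outdir=None,
) -> PipelineResult:
    """Run the full measurement pipeline on 1..k scans of one subject.

    ``picks`` maps landmark names to coordinates in the frame of the first
    scan; without picks the pipeline stops after meshing (dimensions None).
    ``manual`` reference lengths, when given, add a deviation report.  A
    library mismatch raises :exc:`UnmatchedTargetError` (the subject is not a
    known target).  Artifacts are written under ``outdir`` when provided.
    """
    if not scans:
        raise ValueError("need at least one scan")
    config = config or PipelineConfig()
    counts: dict[str, int] = {"input": sum(len(s) for s in scans)}

    bodies, planes = [], []
    for i, scan in enumerate(scans):
        clean = scan.drop_invalid()
        filtered = fused_filter(clean, config.filter)
        if len(filtered) == 0:
            raise RuntimeError(f"stage 'filter' produced an empty cloud for scan {i}")
        body, plane = segment_target(filtered, config.cluster, config.ransac)
        if len(body) == 0:
            raise RuntimeError(f"stage 'segment' removed every point of scan {i}")
        bodies.append(body)
        planes.append(plane)
    counts["filtered"] = sum(len(b) for b in bodies)
    plane = planes[0]
    photographic_distance = float(bodies[0].points[:, 2].mean())

    match = None
    if library is not None:
        match = match_cluster(library, bodies[0], threshold=config.match_threshold)
        if not match.matched:
            raise UnmatchedTargetError(
                f"target cluster unmatched (distance {match.distance:.3g})"
            )

    merged = bodies[0]
    if len(bodies) > 1:
        parts = [bodies[0].points]
        for other in bodies[1:]:
            result = icp(other, bodies[0], config.icp)
            parts.append(apply_transform(other, result.transform).points)
        merged = PointCloud(np.vstack(parts))
        merged = voxel_grid_filter(merged, config.filter)
    counts["registered"] = len(merged)

    smoothed = mls_resample(merged, config.mls)
    oriented = estimate_normals(
        PointCloud(smoothed.points), config.normals
    )
    mesh = greedy_projection_triangulate(oriented, config.gpt)
    counts["mesh_faces"] = len(mesh.faces)

    dimensions = report = None
    if picks is not None:
        body_picks = BodyPicks(dict(picks), photographic_distance)
        dimensions = compute_body_dimensions(body_picks, plane, correction)
        if manual is not None:
            report = deviation_report(dimensions, manual)

    result = PipelineResult(
        merged, plane, mesh, dimensions, report, match, counts, photographic_distance
    )
    if outdir is not None:
        _write_artifacts(result, Path(outdir), config)
    logger.info("pipeline stage counts: %s", counts)
    return result


def _write_artifacts(result: PipelineResult, outdir: Path, config: PipelineConfig) -> None:
    import json

    outdir.mkdir(parents=True, exist_ok=True)
    write_cloud(result.target, outdir / "target.pcd")
    from .core_io import write_mesh

    if len(result.mesh.faces):
        write_mesh(PointCloud(result.mesh.vertices), result.mesh.faces, outdir / "mesh.ply")
    (outdir / "plane.json").write_text(json.dumps({
        "normal": result.plane.normal.tolist(), "offset": result.plane.offset,
    }))
    (outdir / "run.json").write_text(json.dumps({
        "seed": config.seed,
        "stage_counts": result.stage_counts,
        "photographic_distance": result.photographic_distance,
        "mesh": result.mesh_stats,
    }))
    if result.dimensions is not None:
        result.dimensions.as_frame().to_csv(outdir / "dimensions.csv", index=False)
    if result.report is not None:
        result.report.to_csv(outdir / "deviations.csv")
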