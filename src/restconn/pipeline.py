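"""Orchestration: configuration, fixtures, descriptives, and the full run.

The full analysis runs simulate -> prep -> group ICA -> voxel statistics
(one-sample per condition, paired across conditions, ROI definition) ->
Granger causality (network level, then ROI level).  Every table is written
as TSV and every run carries a provenance JSON (config, seed, stage record),
so identical config + seed reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import gcause, gica, netstat, prep, synthio
from .errors import ValidationError
from .grid import VolumeGrid

logger = logging.getLogger(__name__)

#: ROI node order used for the published degree tables.
ROI_NAMES = (
    "dACC", "SMA", "rACC", "dlPFC", "Precuneus", "Parahippocampus", "Insula", "vmPFC"
)


# ---------------------------------------------------------------------------
# packaged fixtures


def _data_path(name: str):
    return resources.files("restconn.data").joinpath(name)


def load_subject_table() -> list[synthio.SubjectRecord]:
    """The packaged 21-subject metadata table (FTND, exhaled CO per session)."""
    df = pd.read_csv(_data_path("table1_subjects.tsv"), sep="\t", dtype={"subject_id": str})
    return [
        synthio.SubjectRecord(r.subject_id, int(r.ftnd), float(r.co_abs_ppm), float(r.co_sat_ppm))
        for r in df.itertuples()
    ]


def load_published_edges(condition: str) -> list[tuple[str, str, float]]:
    """The packaged significant ROI-level edge lists (source, target, F)."""
    fname = {
        "abstinence": "table3_edges_rs_abs.tsv",
        "satiety": "table3_edges_rs_sat.tsv",
    }.get(condition)
    if fname is None:
        raise ValidationError(f"unknown condition {condition!r}")
    df = pd.read_csv(_data_path(fname), sep="\t")
    return [(r.source, r.target, float(r.f_score)) for r in df.itertuples()]


def published_degree_table(condition: str) -> gcause.DegreeTable:
    """Out/in degrees recomputed from the packaged edge list of one condition."""
    graph = gcause.graph_from_edge_list(
        load_published_edges(condition), nodes=ROI_NAMES, condition=condition
    )
    return gcause.out_in_degree(graph)


# ---------------------------------------------------------------------------
# cohort descriptives


@dataclass
class CohortSummary:
    """Mean, sample sd, range and n per metadata variable."""

    stats: dict[str, dict[str, float]]

    def rounded(self, ndigits: int = 2) -> dict[str, dict[str, float]]:
        return {
            var: {k: round(v, ndigits) for k, v in d.items()} for var, d in self.stats.items()
        }


def cohort_summary(records: list[synthio.SubjectRecord]) -> CohortSummary:
    """Descriptive statistics of the subject metadata (sd uses n - 1)."""
    if len(records) < 2:
        raise ValidationError("sample sd undefined for fewer than 2 records")
    out: dict[str, dict[str, float]] = {}
    for var in ("ftnd", "co_abs_ppm", "co_sat_ppm"):
        vals = np.array([getattr(r, var) for r in records], dtype=float)
        out[var] = {
            "mean": float(vals.mean()),
            "sd": float(vals.std(ddof=1)),
            "min": float(vals.min()),
            "max": float(vals.max()),
            "n": float(vals.size),
        }
    return CohortSummary(out)


# ---------------------------------------------------------------------------
# configuration


@dataclass
class RunConfig:
    """Parameters of a full synthetic-cohort analysis run.

    Numeric defaults mirror the study's thresholds: FDR q = 0.01 for the
    one-sample maps, uncorrected p = 0.005 with a 20-voxel extent for the
    paired contrast, FDR q = 0.01 for the network graphs and q = 0.001 for
    the ROI graphs.
    """

    out_dir: str = "restconn_out"
    seed: int = 0
    # cohort
    n_subjects: int = 21
    n_timepoints: int = 150
    grid_dims: tuple[int, int, int] = (24, 28, 24)
    # preprocessing (band-pass/smoothing are scanner-artefact steps; the
    # simulator plants drift-free broadband dynamics, so they default off
    # for synthetic runs and can be enabled for ingested data)
    discard_n: int = 0
    detrend: bool = True
    bandpass: tuple[float, float] | None = None
    smooth_fwhm_mm: float | None = None
    # group ICA
    n_components: int | str = 8
    n_runs: int = 20
    stage_dims: tuple[int, int, int] | None = None
    block_size: int = 7
    match_threshold: float = 0.3
    # voxel statistics
    q_one_sample: float = 0.01
    p_paired_uncorrected: float = 0.005
    min_extent: int = 20
    connectivity: int = 26
    # Granger causality
    gca_order: int | str = "bic"
    gca_max_order: int = 10
    q_network: float = 0.01
    q_roi: float = 0.001
    # zero-phase band-pass of network time courses before GCA; off by
    # default because forward-backward filtering is non-causal and corrupts
    # lag-based inference (see docs/methods.md)
    gca_bandpass_network: bool = False

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise ValidationError("n_subjects must be >= 2")
        for name in ("q_one_sample", "q_network", "q_roi"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValidationError(f"{name} must lie in (0, 1), got {v}")
        if not (0 < self.p_paired_uncorrected < 1):
            raise ValidationError("p_paired_uncorrected must lie in (0, 1)")
        if self.connectivity not in (6, 18, 26):
            raise ValidationError("connectivity must be 6, 18 or 26")
        self.grid_dims = tuple(int(d) for d in self.grid_dims)
        if self.bandpass is not None:
            self.bandpass = tuple(float(v) for v in self.bandpass)
        if self.stage_dims is not None:
            self.stage_dims = tuple(int(d) for d in self.stage_dims)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def truth_for_grid(grid: VolumeGrid, seed: int) -> synthio.SyntheticGroundTruth:
    """Default ground truth rescaled onto an arbitrary (e.g. smoke-test) grid.

    Blob centres and widths are scaled from the default 24 x 28 x 24 extents
    so the planted topography keeps its relative layout on smaller grids.
    """
    ref = synthio.default_grid()
    ratio = np.array(
        [g * s for g, s in zip(grid.dims, grid.voxel_size_mm)]
    ) / np.array([g * s for g, s in zip(ref.dims, ref.voxel_size_mm)])
    blobs = [
        synthio.BlobSpec(
            tuple(np.asarray(b.center_mm) * ratio),
            b.fwhm_mm * float(ratio.mean()),
            b.amplitude,
            b.network,
        )
        for b in synthio.DEFAULT_BLOBS
    ]
    sources = synthio.make_network_templates(grid, blobs)
    return synthio.SyntheticGroundTruth(
        sources=sources,
        causal_by_condition=synthio.default_causal_specs(),
        amplitude_delta={("SN", "abstinence"): 1.2},
        seed=seed,
    )


# ---------------------------------------------------------------------------
# the full run


def _grid_from_dims(dims: tuple[int, int, int]) -> VolumeGrid:
    voxel = (3.0, 3.0, 3.0)
    origin = tuple(-(d - 1) / 2.0 * s for d, s in zip(dims, voxel))
    return VolumeGrid(dims, voxel, origin)


def preprocess_sessions(sessions: list[prep.FmriSession], cfg: RunConfig) -> list[prep.FmriSession]:
    """discard -> detrend -> band-pass -> smooth, as enabled in the config."""
    out = []
    for ses in sessions:
        if cfg.discard_n:
            ses = prep.discard_initial_volumes(ses, cfg.discard_n)
        if cfg.detrend:
            ses = prep.detrend_session(ses)
        if cfg.bandpass is not None:
            ses = prep.bandpass_session(ses, *cfg.bandpass)
        if cfg.smooth_fwhm_mm is not None:
            ses = prep.smooth_session(ses, (cfg.smooth_fwhm_mm,) * 3)
        out.append(ses)
    return out


@dataclass
class RunResult:
    """Everything the full pipeline produces, in memory."""

    config: RunConfig
    truth: synthio.SyntheticGroundTruth
    records: list[synthio.SubjectRecord]
    summary: CohortSummary
    ica: gica.GroupIcaResult
    match: gica.TemplateMatch
    one_sample: dict[tuple[str, str], netstat.StatMap]  # (network, condition)
    paired: dict[str, netstat.StatMap]  # network -> paired map
    clusters: dict[str, list[netstat.Cluster]]
    rois: dict[str, netstat.Roi]
    network_graphs: dict[str, gcause.CausalGraph]
    network_edges: dict[str, list[gcause.CausalEdge]]
    network_order: dict[str, int]
    roi_graphs: dict[str, gcause.CausalGraph] = field(default_factory=dict)
    roi_degrees: dict[str, gcause.DegreeTable] = field(default_factory=dict)


def run_pipeline(cfg: RunConfig, write: bool = True) -> RunResult:
    """Execute the full synthetic-cohort analysis described in the config."""
    cfg.validate()
    grid = _grid_from_dims(cfg.grid_dims)
    truth = truth_for_grid(grid, cfg.seed)
    sessions, records, truth = synthio.make_cohort(cfg.n_subjects, truth, cfg.n_timepoints)
    summary = cohort_summary(records)
    logger.info("simulated %d sessions on grid %s", len(sessions), grid.dims)

    clean = preprocess_sessions(sessions, cfg)
    n_half = cfg.n_subjects
    by_cond = {"abstinence": clean[:n_half], "satiety": clean[n_half:]}

    if cfg.n_components == "estimate":
        # MDL on one session, voxels subsampled (every 3rd) to soften the
        # spatial dependence of neighbouring voxels
        x, _ = gica.session_matrix(clean[0])
        n_comp = max(2, gica.estimate_component_count(x.T[::3]))
    else:
        n_comp = int(cfg.n_components)
    ica = gica.group_ica(
        clean,
        n_components=n_comp,
        n_runs=cfg.n_runs,
        seed=cfg.seed,
        stage_dims=(cfg.stage_dims[:2] + (n_comp,)) if cfg.stage_dims else None,
        block_size=cfg.block_size,
    )
    match = gica.match_components(ica.group.spatial_maps, truth.sources, cfg.match_threshold)

    one_sample: dict[tuple[str, str], netstat.StatMap] = {}
    paired: dict[str, netstat.StatMap] = {}
    clusters: dict[str, list[netstat.Cluster]] = {}
    rois: dict[str, netstat.Roi] = {}
    for network, comp in match.assignments.items():
        z_abs = [netstat.zscore_map(ica.subject_maps[i][comp]) for i in range(n_half)]
        z_sat = [
            netstat.zscore_map(ica.subject_maps[n_half + i][comp]) for i in range(n_half)
        ]
        one_sample[(network, "abstinence")] = netstat.one_sample_ttest(z_abs, grid)
        one_sample[(network, "satiety")] = netstat.one_sample_ttest(z_sat, grid)
        pmap = netstat.paired_ttest(z_abs, z_sat, grid)
        paired[network] = pmap
        found = netstat.extract_clusters(
            pmap, cfg.p_paired_uncorrected, cfg.min_extent, cfg.connectivity  # type: ignore[arg-type]
        )
        clusters[network] = found
        for c in found[:1]:  # strongest cluster per network seeds an ROI
            try:
                rois[network] = netstat.define_roi(c.peak_voxel, grid, network)
            except ValidationError:
                logger.info("peak of %s lies on the boundary; no ROI defined", network)

    network_graphs: dict[str, gcause.CausalGraph] = {}
    network_edges: dict[str, list[gcause.CausalEdge]] = {}
    network_order: dict[str, int] = {}
    names = sorted(match.assignments)
    if len(names) >= 2:
        for condition, cond_sessions in by_cond.items():
            offset = 0 if condition == "abstinence" else n_half
            segs = []
            for i in range(n_half):
                tc = np.stack(
                    [ica.subject_timecourses[offset + i][match.assignments[n]] for n in names]
                )
                if cfg.gca_bandpass_network:
                    tc = np.stack([
                        prep.bandpass_filter(
                            prep.TimeCourse(row, clean[0].tr_s)
                        ).values
                        for row in tc
                    ])
                tc = tc - tc.mean(axis=1, keepdims=True)
                sd = tc.std(axis=1, ddof=1)
                sd[sd == 0] = 1.0
                segs.append(tc / sd[:, None])
            graph, edges, order = gcause.effective_connectivity(
                segs, names, q=cfg.q_network, order=cfg.gca_order,
                max_order=cfg.gca_max_order, condition=condition,
            )
            network_graphs[condition] = graph
            network_edges[condition] = edges
            network_order[condition] = order

    roi_graphs: dict[str, gcause.CausalGraph] = {}
    roi_degrees: dict[str, gcause.DegreeTable] = {}
    roi_names = sorted(rois)
    if len(roi_names) >= 2:
        for condition, cond_sessions in by_cond.items():
            segs = [
                np.stack(
                    [netstat.roi_timeseries(ses, rois[n]).values for n in roi_names]
                )
                for ses in cond_sessions
            ]
            graph, _, _ = gcause.effective_connectivity(
                segs, roi_names, q=cfg.q_roi, order=cfg.gca_order,
                max_order=cfg.gca_max_order, condition=condition,
            )
            roi_graphs[condition] = graph
            roi_degrees[condition] = gcause.out_in_degree(graph)

    result = RunResult(
        config=cfg, truth=truth, records=records, summary=summary, ica=ica,
        match=match, one_sample=one_sample, paired=paired, clusters=clusters,
        rois=rois, network_graphs=network_graphs, network_edges=network_edges,
        network_order=network_order, roi_graphs=roi_graphs, roi_degrees=roi_degrees,
    )
    if write:
        write_results(result)
    return result


# ---------------------------------------------------------------------------
# output


def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_results(result: RunResult) -> Path:
    """Write every declared artifact of a run under the configured out_dir."""
    from . import __version__

    out = Path(result.config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = result.config

    with open(out / "provenance.json", "w", encoding="utf-8") as fh:
        json.dump(
            {
                "config": cfg.to_dict(),
                "config_hash": _config_hash(cfg),
                "seed": cfg.seed,
                "package_version": __version__,
                "stages": ["simulate", "prep", "gica", "netstat", "gcause"],
            },
            fh, indent=2, sort_keys=True, default=str,
        )

    pd.DataFrame(
        [
            {"subject_id": r.subject_id, "ftnd": r.ftnd,
             "co_abs_ppm": r.co_abs_ppm, "co_sat_ppm": r.co_sat_ppm}
            for r in result.records
        ]
    ).to_csv(out / "subjects.tsv", sep="\t", index=False)

    with open(out / "cohort_summary.json", "w", encoding="utf-8") as fh:
        json.dump(result.summary.rounded(), fh, indent=2, sort_keys=True)

    pd.DataFrame(
        {
            "component": np.arange(result.ica.group.n_components),
            "stability": result.ica.stability,
        }
    ).to_csv(out / "ica_stability.tsv", sep="\t", index=False)
    with open(out / "template_match.json", "w", encoding="utf-8") as fh:
        json.dump(
            {
                "assignments": result.match.assignments,
                "scores": result.match.scores,
                "unmatched": result.match.unmatched,
            },
            fh, indent=2, sort_keys=True,
        )

    rows = []
    for network, found in result.clusters.items():
        for c in found:
            rows.append(
                {
                    "network": network,
                    "direction": c.direction,
                    "size_voxels": c.size_voxels,
                    "peak_t": round(c.peak_t, 3),
                    "peak_x_mm": c.peak_mm[0],
                    "peak_y_mm": c.peak_mm[1],
                    "peak_z_mm": c.peak_mm[2],
                }
            )
    pd.DataFrame(
        rows, columns=["network", "direction", "size_voxels", "peak_t",
                       "peak_x_mm", "peak_y_mm", "peak_z_mm"]
    ).to_csv(out / "paired_clusters.tsv", sep="\t", index=False)

    with open(out / "rois.json", "w", encoding="utf-8") as fh:
        json.dump(
            {n: {"center_voxel": r.center_voxel, "n_voxels": len(r.member_voxels)}
             for n, r in result.rois.items()},
            fh, indent=2, sort_keys=True,
        )

    for level, graphs in (("network", result.network_graphs), ("roi", result.roi_graphs)):
        for condition, graph in graphs.items():
            edges = result.network_edges.get(condition, []) if level == "network" else None
            if edges is not None:
                sig = graph.edge_set()
                pd.DataFrame(
                    [
                        {"source": e.source, "target": e.target,
                         "f_score": round(e.f_score, 4), "p_value": e.p_value,
                         "significant": (e.source, e.target) in sig}
                        for e in edges
                    ]
                ).to_csv(out / f"{level}_edges_{condition}.tsv", sep="\t", index=False)
            payload = {
                "nodes": list(graph.nodes),
                "q": graph.q,
                "condition": condition,
                "edges": [
                    {"source": e.source, "target": e.target, "f_score": round(e.f_score, 4)}
                    for e in graph.edges
                ],
            }
            with open(out / f"{level}_graph_{condition}.json", "w", encoding="utf-8") as fh:
                json.dump(payload, fh, indent=2, sort_keys=True)
    for condition, table in result.roi_degrees.items():
        pd.DataFrame(
            {
                "node": table.nodes,
                "out_degree": table.out_degree,
                "in_degree": table.in_degree,
                "out_in": table.out_in,
            }
        ).to_csv(out / f"roi_degrees_{condition}.tsv", sep="\t", index=False)
    return out
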