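"""Synthetic two-condition resting-state fMRI cohorts with known ground truth.

The generator plants (i) Gaussian-blob spatial networks on a small voxel
grid, (ii) stationary vector-autoregressive (VAR) network time courses with a
condition-specific causal structure, and (iii) condition-specific amplitude
scalings, then mixes them linearly with additive Gaussian noise:

    data(v, t) = sum_k scale_k * source_k(v) * tc_k(t) + eps(v, t)

This is the generative model group ICA assumes, so every downstream stage
(unmixing, back-reconstruction, voxelwise tests, Granger causality) can be
checked against the planted truth.  The default cohort emulates the study
conditions: 21 subjects scanned in two sessions (abstinence, then satiety),
150 retained volumes at TR = 2 s, a 24 x 28 x 24 grid of 3 mm voxels, and
four canonical networks (aDMN, pDMN, ECN, SN).

The planted condition contrast mirrors the reported effects at desk scale: a
directed influence SN -> pDMN present only in abstinence, ECN -> SN present
only in satiety, and a 20 % amplitude increase of the SN (strongest at its
insula blob) during abstinence.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import DomainError, StabilityError, ValidationError
from .grid import VolumeGrid
from .prep import FWHM_TO_SIGMA, FmriSession

NETWORK_NAMES = ("aDMN", "pDMN", "ECN", "SN")
CONDITIONS = ("abstinence", "satiety")

#: samples discarded at the start of every VAR simulation to remove
#: initial-condition transients
VAR_BURN_IN = 100


@dataclass(frozen=True)
class BlobSpec:
    """One Gaussian blob of a network template."""

    center_mm: tuple[float, float, float]
    fwhm_mm: float
    amplitude: float
    network: str


@dataclass
class SpatialSourceSet:
    """Per-network voxel amplitude maps plus half-maximum template masks."""

    grid: VolumeGrid
    sources: np.ndarray  # (k, nx, ny, nz)
    names: tuple[str, ...]
    masks: np.ndarray  # (k, nx, ny, nz) bool, voxels above half blob amplitude
    blobs: tuple[BlobSpec, ...] = ()

    def __post_init__(self) -> None:
        self.sources = np.asarray(self.sources, dtype=float)
        if len(self.names) != len(set(self.names)):
            raise ValidationError(f"network names must be unique: {self.names}")
        if self.sources.shape[0] != len(self.names):
            raise ValidationError("one source map per network name required")
        if not np.all(np.isfinite(self.sources)):
            raise ValidationError("source maps must be finite")
        for k, name in enumerate(self.names):
            if not np.any(self.sources[k] > 0):
                raise ValidationError(f"network {name!r} has no strictly positive voxel")

    @property
    def n_networks(self) -> int:
        return len(self.names)

    def flat_maps(self) -> np.ndarray:
        """(k, n_voxels) view of the source maps."""
        return self.sources.reshape(self.n_networks, -1)

    def network_blobs(self, name: str) -> list[BlobSpec]:
        return [b for b in self.blobs if b.network == name]


@dataclass
class CausalSpec:
    """A stationary VAR(p) specification.

    ``coeffs[lag][target][source]`` is the influence of ``source`` at lag
    ``lag + 1`` on ``target``; ``noise_sd`` is the innovation standard
    deviation per node.
    """

    order: int
    coeffs: np.ndarray  # (p, k, k)
    noise_sd: np.ndarray  # (k,)

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        self.noise_sd = np.atleast_1d(np.asarray(self.noise_sd, dtype=float))
        if self.order < 1 or self.coeffs.shape[0] != self.order:
            raise ValidationError(f"coeffs must have shape (order, k, k); got {self.coeffs.shape}")
        k = self.coeffs.shape[1]
        if self.coeffs.shape != (self.order, k, k):
            raise ValidationError(f"coeffs must be (p, k, k), got {self.coeffs.shape}")
        if self.noise_sd.shape == (1,):
            self.noise_sd = np.full(k, float(self.noise_sd[0]))
        if self.noise_sd.shape != (k,):
            raise ValidationError("noise_sd must be scalar or one value per node")
        if np.any(self.noise_sd <= 0):
            raise ValidationError(f"noise_sd must be positive, got {self.noise_sd}")
        if not np.all(np.isfinite(self.coeffs)):
            raise ValidationError("VAR coefficients must be finite")
        rho = self.spectral_radius()
        if rho >= 1.0:
            raise StabilityError(f"VAR companion spectral radius {rho:.3f} >= 1 (non-stationary)")

    @property
    def n_nodes(self) -> int:
        return self.coeffs.shape[1]

    def companion(self) -> np.ndarray:
        """(p*k, p*k) companion-form transition matrix."""
        p, k = self.order, self.n_nodes
        comp = np.zeros((p * k, p * k))
        comp[:k, :] = np.concatenate([self.coeffs[j] for j in range(p)], axis=1)
        if p > 1:
            comp[k:, : (p - 1) * k] = np.eye((p - 1) * k)
        return comp

    def spectral_radius(self) -> float:
        return float(np.max(np.abs(np.linalg.eigvals(self.companion()))))

    def cross_edges(self, names=NETWORK_NAMES, tol: float = 0.0) -> set[tuple[str, str]]:
        """Directed (source, target) pairs with any nonzero off-diagonal lag."""
        edges = set()
        for tgt in range(self.n_nodes):
            for src in range(self.n_nodes):
                if src != tgt and np.any(np.abs(self.coeffs[:, tgt, src]) > tol):
                    edges.add((names[src], names[tgt]))
        return edges


@dataclass(frozen=True)
class SubjectRecord:
    """Metadata for one subject: nicotine-dependence score and exhaled CO."""

    subject_id: str
    ftnd: int
    co_abs_ppm: float
    co_sat_ppm: float

    def __post_init__(self) -> None:
        if not (0 <= self.ftnd <= 10):
            raise ValidationError(f"FTND must be in [0, 10], got {self.ftnd}")
        if self.co_abs_ppm <= 0 or self.co_sat_ppm <= 0:
            raise ValidationError("CO levels must be positive")


@dataclass
class SyntheticGroundTruth:
    """Everything needed to score recovery of the planted structure."""

    sources: SpatialSourceSet
    causal_by_condition: dict[str, CausalSpec]
    amplitude_delta: dict[tuple[str, str], float]
    seed: int
    noise_sd: float = 1.0
    subject_jitter_sd: float = 0.1
    tr_s: float = 2.0
    #: filled in by make_cohort: (subject_id, condition) -> (k, T) generator output
    true_timecourses: dict[tuple[str, str], np.ndarray] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        missing = set(CONDITIONS) - set(self.causal_by_condition)
        if missing:
            raise ValidationError(f"causal spec missing for conditions {sorted(missing)}")
        if any(v <= 0 for v in self.amplitude_delta.values()):
            raise ValidationError("amplitude scale factors must be positive")

    def amplitude_scales(self, condition: str) -> np.ndarray:
        return np.array(
            [self.amplitude_delta.get((name, condition), 1.0) for name in self.sources.names]
        )


def make_network_templates(
    grid: VolumeGrid,
    blob_specs: list[tuple[tuple[float, float, float], float, float, str]] | list[BlobSpec],
) -> SpatialSourceSet:
    """Build per-network amplitude maps as sums of Gaussian blobs.

    Each blob is evaluated at voxel centers; a network's binary template mask
    is the union of its blobs' above-half-amplitude regions.
    """
    blobs = [b if isinstance(b, BlobSpec) else BlobSpec(*b) for b in blob_specs]
    if not blobs:
        raise ValidationError("at least one blob is required")
    names: list[str] = []
    for b in blobs:
        if b.fwhm_mm <= 0:
            raise ValidationError(f"blob FWHM must be positive, got {b.fwhm_mm}")
        if not grid.contains_mm(b.center_mm):
            raise DomainError(f"blob center {b.center_mm} lies outside the grid")
        if b.network not in names:
            names.append(b.network)
    centers = grid.voxel_centers_mm()  # (nx, ny, nz, 3)
    k = len(names)
    sources = np.zeros((k,) + grid.dims)
    masks = np.zeros((k,) + grid.dims, dtype=bool)
    for b in blobs:
        ki = names.index(b.network)
        sigma = b.fwhm_mm * FWHM_TO_SIGMA
        d2 = np.sum((centers - np.asarray(b.center_mm)) ** 2, axis=-1)
        blob_map = b.amplitude * np.exp(-d2 / (2.0 * sigma**2))
        sources[ki] += blob_map
        masks[ki] |= blob_map > 0.5 * b.amplitude
    return SpatialSourceSet(grid, sources, tuple(names), masks, tuple(blobs))


def blob_halfmax_mask(grid: VolumeGrid, blob: BlobSpec) -> np.ndarray:
    """Boolean mask of voxels above half of one blob's peak amplitude."""
    sigma = blob.fwhm_mm * FWHM_TO_SIGMA
    d2 = np.sum((grid.voxel_centers_mm() - np.asarray(blob.center_mm)) ** 2, axis=-1)
    return np.exp(-d2 / (2.0 * sigma**2)) > 0.5


def simulate_var_timecourses(n_timepoints: int, spec: CausalSpec, seed: int) -> np.ndarray:
    """Simulate a stationary VAR(p) process; returns (k, n_timepoints).

    The first ``VAR_BURN_IN`` samples are generated and discarded so the
    returned segment is free of initial-condition transients.  Identical seed
    gives identical output.
    """
    if n_timepoints <= 10 * spec.order:
        raise ValidationError(
            f"n_timepoints={n_timepoints} too short for order {spec.order} (need > 10*p)"
        )
    rng = np.random.default_rng(seed)
    p, k = spec.order, spec.n_nodes
    total = n_timepoints + VAR_BURN_IN
    x = np.zeros((k, total + p))
    innovations = rng.standard_normal((k, total)) * spec.noise_sd[:, None]
    for t in range(p, total + p):
        acc = innovations[:, t - p]
        for j in range(p):
            acc = acc + spec.coeffs[j] @ x[:, t - 1 - j]
        x[:, t] = acc
    return x[:, p + VAR_BURN_IN:].copy()


def synthesize_session(
    sources: SpatialSourceSet,
    timecourses: np.ndarray,
    noise_sd: float,
    amplitude_scales: np.ndarray | None = None,
    seed: int = 0,
    subject_id: str = "sub-000",
    condition: str = "abstinence",
    tr_s: float = 2.0,
) -> FmriSession:
    """Mix spatial sources with time courses and add iid Gaussian noise."""
    tcs = np.asarray(timecourses, dtype=float)
    if tcs.ndim != 2 or tcs.shape[0] != sources.n_networks:
        raise ValidationError(
            f"need one time course per source: {sources.n_networks} sources, "
            f"time course shape {tcs.shape}"
        )
    if noise_sd < 0:
        raise ValidationError(f"noise_sd must be >= 0, got {noise_sd}")
    scales = (
        np.ones(sources.n_networks)
        if amplitude_scales is None
        else np.asarray(amplitude_scales, dtype=float)
    )
    if scales.shape != (sources.n_networks,):
        raise ValidationError("one amplitude scale per source required")
    flat = sources.flat_maps()  # (k, V)
    data = (flat * scales[:, None]).T @ tcs  # (V, T)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        data = data + rng.standard_normal(data.shape) * noise_sd
    return FmriSession(
        subject_id=subject_id,
        condition=condition,  # type: ignore[arg-type]
        grid=sources.grid,
        tr_s=tr_s,
        data=data.reshape(sources.grid.dims + (tcs.shape[1],)),
    )


def default_grid() -> VolumeGrid:
    """24 x 28 x 24 voxels of 3 mm, centered on the world origin."""
    dims = (24, 28, 24)
    voxel = (3.0, 3.0, 3.0)
    origin = tuple(-(d - 1) / 2.0 * s for d, s in zip(dims, voxel))
    return VolumeGrid(dims, voxel, origin)


#: Two blobs per network at fixed loci loosely mimicking the canonical
#: resting-state topographies (medial prefrontal / anterior cingulate for
#: aDMN, posterior cingulate + lateral parietal for pDMN, bilateral
#: dorsolateral prefrontal for ECN, right insula + dorsal ACC for SN).  The
#: insula blob carries the SN's largest amplitude.
DEFAULT_BLOBS: tuple[BlobSpec, ...] = (
    BlobSpec((-3.0, 30.0, 3.0), 14.0, 2.5, "aDMN"),
    BlobSpec((3.0, 27.0, -12.0), 12.0, 2.0, "aDMN"),
    BlobSpec((0.0, -33.0, 15.0), 14.0, 2.5, "pDMN"),
    BlobSpec((-24.0, -33.0, 24.0), 12.0, 2.0, "pDMN"),
    BlobSpec((-27.0, 21.0, 21.0), 13.0, 2.5, "ECN"),
    BlobSpec((27.0, 21.0, 21.0), 13.0, 2.0, "ECN"),
    BlobSpec((27.0, 9.0, -3.0), 13.0, 3.0, "SN"),
    BlobSpec((0.0, 12.0, 18.0), 12.0, 2.0, "SN"),
)

#: Node order for the default causal specs.
_DIAG_LAG1 = np.diag([0.35, 0.30, 0.32, 0.34])
_DIAG_LAG2 = np.diag([0.15, 0.20, 0.18, 0.12])

#: Planted cross-network coefficient (lag 1).
DEFAULT_CROSS_COEF = 0.4


def default_causal_specs(cross_coef: float = DEFAULT_CROSS_COEF) -> dict[str, CausalSpec]:
    """Condition-specific VAR(2) truths.

    Abstinence carries SN -> pDMN; satiety replaces it with ECN -> SN.  Node
    order is (aDMN, pDMN, ECN, SN).
    """
    i = {name: idx for idx, name in enumerate(NETWORK_NAMES)}
    a1_abs = _DIAG_LAG1.copy()
    a1_abs[i["pDMN"], i["SN"]] = cross_coef
    a1_sat = _DIAG_LAG1.copy()
    a1_sat[i["SN"], i["ECN"]] = cross_coef
    return {
        "abstinence": CausalSpec(2, np.stack([a1_abs, _DIAG_LAG2]), np.ones(4)),
        "satiety": CausalSpec(2, np.stack([a1_sat, _DIAG_LAG2]), np.ones(4)),
    }


def default_truth(seed: int = 0) -> SyntheticGroundTruth:
    """The default study conditions: four networks, VAR(2) contrast, SN +20 %."""
    sources = make_network_templates(default_grid(), list(DEFAULT_BLOBS))
    return SyntheticGroundTruth(
        sources=sources,
        causal_by_condition=default_causal_specs(),
        amplitude_delta={("SN", "abstinence"): 1.2},
        seed=seed,
    )


def _subject_seeds(seed: int, n_subjects: int) -> list[np.random.SeedSequence]:
    return np.random.SeedSequence(seed).spawn(n_subjects + 1)


def make_cohort(
    n_subjects: int = 21,
    truth: SyntheticGroundTruth | None = None,
    n_timepoints: int = 150,
) -> tuple[list[FmriSession], list[SubjectRecord], SyntheticGroundTruth]:
    """Generate a full two-condition cohort with per-subject variability.

    Returns sessions ordered condition-major (all abstinence sessions, then
    all satiety sessions, each in subject order), the metadata records, and
    the ground truth (with per-subject true time courses attached, see
    :func:`cohort_true_timecourses`).
    """
    if n_subjects < 2:
        raise ValidationError("need at least 2 subjects (paired test undefined otherwise)")
    if truth is None:
        truth = default_truth()
    seqs = _subject_seeds(truth.seed, n_subjects)
    meta_rng = np.random.default_rng(seqs[-1])
    sessions: dict[str, list[FmriSession]] = {c: [] for c in CONDITIONS}
    records: list[SubjectRecord] = []
    true_tcs: dict[tuple[str, str], np.ndarray] = {}
    for s in range(n_subjects):
        subject_id = f"sub-{s + 1:03d}"
        sub_rng = np.random.default_rng(seqs[s])
        # per-subject multiplicative amplitude jitter, shared across conditions
        jitter = np.exp(sub_rng.normal(0.0, truth.subject_jitter_sd, truth.sources.n_networks))
        for condition in CONDITIONS:
            tc_seed, noise_seed = sub_rng.integers(0, 2**31 - 1, size=2)
            tcs = simulate_var_timecourses(
                n_timepoints, truth.causal_by_condition[condition], int(tc_seed)
            )
            true_tcs[(subject_id, condition)] = tcs
            scales = truth.amplitude_scales(condition) * jitter
            sessions[condition].append(
                synthesize_session(
                    truth.sources,
                    tcs,
                    truth.noise_sd,
                    scales,
                    seed=int(noise_seed),
                    subject_id=subject_id,
                    condition=condition,
                    tr_s=truth.tr_s,
                )
            )
        records.append(_draw_subject_record(subject_id, meta_rng))
    truth = dataclasses.replace(truth, true_timecourses=true_tcs)
    return sessions["abstinence"] + sessions["satiety"], records, truth


def _draw_subject_record(subject_id: str, rng: np.random.Generator) -> SubjectRecord:
    """FTND ~ U{5..8}; CO_abs ~ N(9.6, 3.5^2) truncated > 0; CO_sat strictly above."""
    ftnd = int(rng.integers(5, 9))
    co_abs = 0.0
    while co_abs < 1.0:
        co_abs = rng.normal(9.6, 3.5)
    increment = 0.0
    while increment < 1.0:
        increment = rng.normal(13.2, 5.0)
    return SubjectRecord(
        subject_id=subject_id,
        ftnd=ftnd,
        co_abs_ppm=round(co_abs, 1),
        co_sat_ppm=round(co_abs + increment, 1),
    )


# ---------------------------------------------------------------------------
# on-disk representation


def write_cohort(
    out_dir: str | Path,
    sessions: list[FmriSession],
    records: list[SubjectRecord],
    truth: SyntheticGroundTruth,
) -> None:
    """Persist a cohort: NIfTI-1 per session, subjects.tsv, and truth files."""
    import nibabel as nib

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for ses in sessions:
        img = nib.Nifti1Image(ses.data.astype(np.float32), ses.grid.affine)
        img.header.set_zooms(ses.grid.voxel_size_mm + (ses.tr_s,))
        nib.save(img, out / f"{ses.subject_id}_{ses.condition}.nii.gz")
    with open(out / "subjects.tsv", "w", encoding="utf-8") as fh:
        fh.write("subject_id\tftnd\tco_abs_ppm\tco_sat_ppm\n")
        for r in records:
            fh.write(f"{r.subject_id}\t{r.ftnd}\t{r.co_abs_ppm}\t{r.co_sat_ppm}\n")
    src = truth.sources
    nib.save(
        nib.Nifti1Image(np.moveaxis(src.sources, 0, -1).astype(np.float32), src.grid.affine),
        out / "truth_sources.nii.gz",
    )
    payload = {
        "seed": truth.seed,
        "noise_sd": truth.noise_sd,
        "tr_s": truth.tr_s,
        "networks": list(src.names),
        "amplitude_delta": {f"{n}|{c}": v for (n, c), v in truth.amplitude_delta.items()},
        "causal_by_condition": {
            c: {
                "order": spec.order,
                "coeffs": spec.coeffs.tolist(),
                "noise_sd": spec.noise_sd.tolist(),
            }
            for c, spec in truth.causal_by_condition.items()
        },
    }
    with open(out / "truth.json", "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
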