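"""Group spatial ICA with temporal concatenation and stability selection.

The decomposition follows the temporal-concatenation group-ICA recipe: each
session's time dimension is PCA-reduced, sessions are concatenated in a fixed
order (all first-condition sessions, then all second-condition sessions) and
reduced again in two further stages, and the final reduced matrix is unmixed
with Infomax ICA.  Because random initialisation makes single ICA runs
unstable, the decomposition is repeated from many seeds and the pooled
components are clustered; each cluster's centrotype is kept as the stable
component (ICASSO).  Per-session spatial maps and time courses are recovered
by back-reconstruction through the stored stage projections.

Conventions: spatial maps are stored as rows over voxels, fixed to unit
variance and non-negative skewness; time courses follow from the mixing
matrix under that convention.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .errors import RankError, ValidationError
from .prep import FmriSession
from .synthio import SpatialSourceSet

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# containers


@dataclass
class ComponentSet:
    """A set of spatial components with their reduced-space mixing."""

    spatial_maps: np.ndarray  # (k, V) unit-variance, nonneg-skew rows
    mixing: np.ndarray  # (d, k): reduced data ~ mixing @ spatial_maps
    unmixing: np.ndarray  # (k, d)
    n_components: int
    converged: bool = True
    identifiable: bool = True

    def __post_init__(self) -> None:
        if self.spatial_maps.shape[0] != self.n_components:
            raise ValidationError("map count must equal n_components")
        if not (np.all(np.isfinite(self.spatial_maps)) and np.all(np.isfinite(self.mixing))):
            raise ValidationError("component set contains non-finite values")


@dataclass
class StageProjections:
    """Stored PCA projections for the three reduction stages."""

    session_proj: list[np.ndarray]  # per session: (d1, T) orthonormal rows
    session_mean: list[np.ndarray]  # per session: (V,) voxel means removed
    block_proj: list[np.ndarray]  # per block: (d2, b*d1)
    block_members: list[list[int]]  # session indices per block
    final_proj: np.ndarray  # (d3, n_blocks*d2)
    stage_dims: tuple[int, int, int]


@dataclass
class GroupIcaResult:
    """Group components plus back-reconstructed per-session quantities."""

    group: ComponentSet
    subject_maps: list[np.ndarray]  # per session: (k, V)
    subject_timecourses: list[np.ndarray]  # per session: (k, T)
    stability: np.ndarray  # (k,) in [0, 1]
    reduction: StageProjections

    def __post_init__(self) -> None:
        if np.any(self.stability < 0) or np.any(self.stability > 1):
            raise ValidationError("stability indices must lie in [0, 1]")


@dataclass
class TemplateMatch:
    """Assignment of components to named network templates."""

    assignments: dict[str, int]  # network name -> component index
    scores: dict[str, float]
    unmatched: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        idx = list(self.assignments.values())
        if len(idx) != len(set(idx)):
            raise ValidationError("assigned component indices must be distinct")


# ---------------------------------------------------------------------------
# component-count estimation (information-theoretic order selection)


def mdl_curve(eigenvalues: np.ndarray, n_obs: int) -> np.ndarray:
    """Description length for k = 0 .. V-1 signal components.

    Uses the eigenvalue form: the likelihood term is the log-ratio of the
    geometric to the arithmetic mean of the trailing eigenvalues, and the
    penalty counts the free parameters of a k-dimensional signal subspace,
    0.5 * k * (2V - k) * ln N.
    """
    lam = np.sort(np.asarray(eigenvalues, dtype=float))[::-1]
    v = lam.size
    if np.any(lam <= 0):
        bad = int(np.argmax(lam <= 0))
        raise RankError(
            f"covariance is rank deficient: eigenvalue {bad} of {v} is not positive"
        )
    log_lam = np.log(lam)
    out = np.empty(v)
    for k in range(v):
        tail = lam[k:]
        geo = np.mean(log_lam[k:])
        arith = np.log(np.mean(tail))
        out[k] = -n_obs * (v - k) * (geo - arith) + 0.5 * k * (2 * v - k) * np.log(n_obs)
    return out


def estimate_component_count(data: np.ndarray) -> int:
    """Minimum-description-length estimate of the number of components.

    ``data`` is observations x variables; the estimate is the argmin of the
    MDL curve over the eigenvalues of the sample covariance of the variables.
    """
    x = np.asarray(data, dtype=float)
    n, v = x.shape
    if v < 2:
        raise ValidationError("need at least 2 variables")
    if n <= v:
        raise ValidationError(f"need more observations ({n}) than variables ({v})")
    xc = x - x.mean(axis=0)
    cov = xc.T @ xc / (n - 1)
    lam = np.linalg.eigvalsh(cov)[::-1]
    if lam[-1] <= max(1e-12 * lam[0], 0.0):
        bad = int(np.argmax(lam <= 1e-12 * lam[0]))
        raise RankError(f"covariance is rank deficient at dimension {bad} of {v}")
    return int(np.argmin(mdl_curve(lam, n)))


# ---------------------------------------------------------------------------
# staged PCA reduction


def _top_rows(x: np.ndarray, d: int) -> np.ndarray:
    """Orthonormal (d, n_rows) projection onto the top-d row space of x.

    Computed from the small Gram matrix x @ x.T, so the cost is governed by
    the row count, not the voxel count.
    """
    gram = x @ x.T
    lam, vec = np.linalg.eigh(gram)
    order = np.argsort(lam)[::-1][:d]
    return vec[:, order].T


def session_matrix(session: FmriSession) -> tuple[np.ndarray, np.ndarray]:
    """(T, V) matrix with per-voxel time means removed; returns (data, means)."""
    x = session.voxels_by_time().T.astype(float)  # (T, V)
    mean = x.mean(axis=0)
    return x - mean, mean


def reduce_stagewise_pca(
    sessions: list[FmriSession],
    stage_dims: tuple[int, int, int],
    block_size: int = 7,
) -> tuple[np.ndarray, StageProjections]:
    """Three-stage PCA over temporally concatenated sessions.

    Stage 1 reduces each session's time dimension to ``d1``; stage 2 stacks
    fixed-size blocks of sessions and reduces to ``d2``; stage 3 stacks all
    blocks and reduces to ``d3``.  All projections are stored so individual
    sessions can be recovered by back-reconstruction.
    """
    d1, d2, d3 = stage_dims
    if not (d1 >= d2 >= d3 >= 2):
        raise ValidationError(f"stage dims must satisfy d1 >= d2 >= d3 >= 2, got {stage_dims}")
    if not sessions:
        raise ValidationError("no sessions given")
    t_min = min(s.n_timepoints for s in sessions)
    if d1 > t_min:
        raise ValidationError(f"d1={d1} exceeds the shortest session length {t_min}")

    session_proj: list[np.ndarray] = []
    session_mean: list[np.ndarray] = []
    reduced1: list[np.ndarray] = []
    for ses in sessions:
        x, mean = session_matrix(ses)  # (T, V)
        f = _top_rows(x, d1)  # (d1, T)
        session_proj.append(f)
        session_mean.append(mean)
        reduced1.append(f @ x)  # (d1, V)

    n = len(sessions)
    block_members = [list(range(i, min(i + block_size, n))) for i in range(0, n, block_size)]
    block_proj: list[np.ndarray] = []
    reduced2: list[np.ndarray] = []
    for members in block_members:
        stacked = np.concatenate([reduced1[i] for i in members], axis=0)
        d2_eff = min(d2, stacked.shape[0])
        g = _top_rows(stacked, d2_eff)
        block_proj.append(g)
        reduced2.append(g @ stacked)

    stacked_all = np.concatenate(reduced2, axis=0)
    if d3 > stacked_all.shape[0]:
        raise ValidationError(f"d3={d3} exceeds available dimensions {stacked_all.shape[0]}")
    h = _top_rows(stacked_all, d3)
    group = h @ stacked_all  # (d3, V)
    proj = StageProjections(session_proj, session_mean, block_proj, block_members, h, stage_dims)
    return group, proj


# ---------------------------------------------------------------------------
# Infomax ICA


def _fix_sign_scale(maps: np.ndarray, mixing: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unit-variance, non-negative-skew spatial maps; mixing rescaled to match."""
    sd = maps.std(axis=1, ddof=0)
    sd[sd == 0] = 1.0
    sign = np.sign(((maps - maps.mean(axis=1, keepdims=True)) ** 3).mean(axis=1))
    sign[sign == 0] = 1.0
    factor = sign / sd
    return maps * factor[:, None], mixing / factor[None, :]


def _whiten(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Whiten rows of x over columns; returns (z, sphere, unsphere)."""
    mu = x.mean(axis=1, keepdims=True)
    xc = x - mu
    cov = xc @ xc.T / xc.shape[1]
    lam, vec = np.linalg.eigh(cov)
    if lam[0] <= 1e-12 * lam[-1]:
        raise RankError("reduced data covariance is rank deficient; lower the stage dims")
    sphere = (vec / np.sqrt(lam)) @ vec.T  # symmetric whitening
    unsphere = (vec * np.sqrt(lam)) @ vec.T
    return sphere @ xc, sphere, unsphere


def infomax_ica(
    reduced: np.ndarray,
    seed: int,
    learning_rate: float = 0.01,
    max_iter: int = 512,
    tol: float = 1e-5,
    block_size: int = 256,
) -> ComponentSet:
    """Natural-gradient Infomax ICA with a logistic nonlinearity.

    ``reduced`` is (k, V): k reduced time dimensions over V voxel samples.
    The data are whitened internally; the returned spatial maps are the
    estimated independent sources over voxels.  Non-convergence within
    ``max_iter`` sweeps is reported via a warning and the ``converged`` flag.
    Two Gaussian sources are flagged non-identifiable via ``identifiable``.
    """
    x = np.asarray(reduced, dtype=float)
    k, n_samp = x.shape
    if k < 2:
        raise ValidationError("need at least 2 reduced dimensions")
    z, sphere, unsphere = _whiten(x)
    rng = np.random.default_rng(seed)
    w = np.linalg.qr(rng.standard_normal((k, k)))[0]
    eye = np.eye(k)
    lr = learning_rate
    old_dw = None
    old_change = 0.0
    converged = False
    for sweep in range(max_iter):
        w_old = w.copy()
        perm = rng.permutation(n_samp)
        for start in range(0, n_samp, block_size):
            idx = perm[start : start + block_size]
            u = w @ z[:, idx]
            y = 1.0 / (1.0 + np.exp(-u))
            grad = eye + ((1.0 - 2.0 * y) @ u.T) / idx.size
            w = w + lr * grad @ w
            if np.max(np.abs(w)) > 1e8:  # blow-up guard: restart colder
                lr *= 0.5
                w = np.linalg.qr(rng.standard_normal((k, k)))[0]
                break
        dw = w - w_old
        change = float((dw**2).sum())
        # anneal only when the update direction turns by more than 60 deg;
        # stochastic sweep-to-sweep jitter alone must not shrink the rate
        if old_dw is not None and change > 0 and old_change > 0:
            cosang = float((dw * old_dw).sum()) / np.sqrt(change * old_change)
            if np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))) > 60.0:
                lr *= 0.9
                old_dw, old_change = dw, change
        else:
            old_dw, old_change = dw, change
        if np.sqrt(change) < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"Infomax did not converge within {max_iter} sweeps "
            f"(last weight change {np.sqrt(change):.2e})",
            RuntimeWarning,
            stacklevel=2,
        )
    maps = w @ z  # (k, V)
    # excess kurtosis near zero for every source => rotation is not identified
    mc = maps - maps.mean(axis=1, keepdims=True)
    m2 = (mc**2).mean(axis=1)
    kurt = (mc**4).mean(axis=1) / m2**2 - 3.0
    identifiable = bool(np.any(np.abs(kurt) > 0.5))
    unmixing = w @ sphere  # (k, k) on the reduced space
    mixing = np.linalg.inv(unmixing) if np.isfinite(np.linalg.cond(unmixing)) else np.linalg.pinv(unmixing)
    maps, mixing = _fix_sign_scale(maps, mixing)
    return ComponentSet(
        spatial_maps=maps,
        mixing=mixing,
        unmixing=np.linalg.pinv(mixing),
        n_components=k,
        converged=converged,
        identifiable=identifiable,
    )


# ---------------------------------------------------------------------------
# ICASSO stability selection


def _abs_corr(maps: np.ndarray) -> np.ndarray:
    """|Pearson correlation| between all map rows."""
    c = np.corrcoef(maps)
    return np.clip(np.abs(c), 0.0, 1.0)


def icasso_select(
    runs: list[ComponentSet], n_components: int, reduced: np.ndarray | None = None
) -> tuple[ComponentSet, np.ndarray]:
    """Cluster pooled components across runs and keep cluster centrotypes.

    Dissimilarity is 1 - |spatial correlation| (sign-invariant); clusters come
    from average-linkage agglomeration cut at ``n_components`` clusters.  The
    centrotype of a cluster is the member with the largest summed similarity
    to its cluster mates; the stability index is the mean intra-cluster
    similarity minus the mean similarity to the nearest other cluster,
    clipped to [0, 1].

    When ``reduced`` (the stage-3 matrix) is given, the returned mixing is
    re-estimated by least squares of the reduced data on the centrotype maps,
    which keeps back-reconstruction consistent with the selected maps.
    """
    if len(runs) < 2:
        raise ValidationError("ICASSO needs at least 2 runs")
    for r in runs:
        if r.n_components != n_components:
            raise ValidationError(
                f"every run must have {n_components} components, got {r.n_components}"
            )
    pooled = np.concatenate([r.spatial_maps for r in runs], axis=0)
    sim = _abs_corr(pooled)
    dist = 1.0 - sim
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(z, t=n_components, criterion="maxclust")

    centro_idx = np.empty(n_components, dtype=int)
    stability = np.empty(n_components)
    for c in range(1, n_components + 1):
        members = np.flatnonzero(labels == c)
        sub = sim[np.ix_(members, members)]
        centro_idx[c - 1] = members[int(np.argmax(sub.sum(axis=1)))]
        if members.size == 1:
            intra = 1.0
        else:
            intra = (sub.sum() - members.size) / (members.size * (members.size - 1))
        extra = 0.0
        for c2 in range(1, n_components + 1):
            if c2 == c:
                continue
            others = np.flatnonzero(labels == c2)
            extra = max(extra, float(sim[np.ix_(members, others)].mean()))
        stability[c - 1] = np.clip(intra - extra, 0.0, 1.0)

    # deterministic component order: by decreasing stability, ties by index
    order = np.lexsort((centro_idx, -stability))
    centro_idx, stability = centro_idx[order], stability[order]
    maps = pooled[centro_idx].copy()

    if reduced is not None:
        xc = reduced - reduced.mean(axis=1, keepdims=True)
        mixing = (np.linalg.lstsq(maps.T, xc.T, rcond=None)[0]).T  # (d, k)
    else:
        mixing = np.linalg.pinv(maps @ maps.T) @ maps  # placeholder in map space
        mixing = mixing.T
    maps, mixing = _fix_sign_scale(maps, mixing)
    selected = ComponentSet(
        spatial_maps=maps,
        mixing=mixing,
        unmixing=np.linalg.pinv(mixing),
        n_components=n_components,
        converged=all(r.converged for r in runs),
    )
    return selected, stability


# ---------------------------------------------------------------------------
# back-reconstruction


def back_reconstruct(
    result: ComponentSet,
    projections: StageProjections,
    sessions: list[FmriSession],
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Per-session spatial maps and time courses from the group decomposition.

    The session's partition of the group mixing matrix is propagated back
    through the stored stage projections (orthonormal rows, so the
    pseudo-inverse is the transpose): the session time courses are
    ``F_i^T [G_b^T (H^T A)_b]_i`` and the session maps follow by regressing
    the session data on those time courses.
    """
    if len(sessions) != len(projections.session_proj):
        raise ValidationError(
            f"{len(sessions)} sessions but projections stored for "
            f"{len(projections.session_proj)}"
        )
    d1 = projections.stage_dims[0]
    a_group = result.mixing  # (d3, k)
    stacked2 = projections.final_proj.T @ a_group  # (n_blocks*d2, k)
    maps_out: list[np.ndarray] = []
    tcs_out: list[np.ndarray] = []
    offset = 0
    session_tc: dict[int, np.ndarray] = {}
    for b, members in enumerate(projections.block_members):
        g = projections.block_proj[b]
        rows = g.shape[0]
        block_part = stacked2[offset : offset + rows]  # (d2_eff, k)
        offset += rows
        stacked1 = g.T @ block_part  # (len(members)*d1, k)
        for slot, sess_idx in enumerate(members):
            part = stacked1[slot * d1 : (slot + 1) * d1]  # (d1, k)
            session_tc[sess_idx] = projections.session_proj[sess_idx].T @ part  # (T, k)
    for i, ses in enumerate(sessions):
        a_i = session_tc[i]  # (T, k)
        x, _ = session_matrix(ses)  # (T, V)
        s_i, *_ = np.linalg.lstsq(a_i, x, rcond=None)  # (k, V)
        maps_out.append(s_i)
        tcs_out.append(a_i.T)  # (k, T)
    return maps_out, tcs_out


# ---------------------------------------------------------------------------
# template matching


def match_components(
    maps: np.ndarray,
    templates: SpatialSourceSet,
    threshold: float = 0.3,
) -> TemplateMatch:
    """Greedy best-first assignment of components to network templates.

    The score is the Pearson correlation between a component map and the
    binary template mask.  Pairs are assigned in decreasing score order with
    ties broken toward the lower component index; templates whose best
    remaining score falls below ``threshold`` are reported unmatched.
    """
    m = np.asarray(maps, dtype=float)
    if m.ndim != 2:
        m = m.reshape(m.shape[0], -1)
    n_comp = m.shape[0]
    n_templ = templates.n_networks
    if n_comp < n_templ:
        raise ValidationError(f"{n_comp} components cannot cover {n_templ} templates")
    ref = templates.masks.reshape(n_templ, -1).astype(float)
    scores = np.empty((n_templ, n_comp))
    for t in range(n_templ):
        for c in range(n_comp):
            scores[t, c] = np.corrcoef(ref[t], m[c])[0, 1]
    assignments: dict[str, int] = {}
    matched_scores: dict[str, float] = {}
    unmatched: list[str] = []
    free_t = set(range(n_templ))
    free_c = set(range(n_comp))
    while free_t:
        best = None
        for t in sorted(free_t):
            for c in sorted(free_c):  # ascending index => lower index wins ties
                s = scores[t, c]
                if best is None or s > best[0] + 1e-15:
                    best = (s, t, c)
        s, t, c = best
        free_t.remove(t)
        name = templates.names[t]
        if s < threshold:
            unmatched.append(name)
            continue
        free_c.remove(c)
        assignments[name] = c
        matched_scores[name] = float(s)
    return TemplateMatch(assignments, matched_scores, unmatched)


# ---------------------------------------------------------------------------
# driver


def group_ica(
    sessions: list[FmriSession],
    n_components: int,
    n_runs: int = 20,
    seed: int = 0,
    stage_dims: tuple[int, int, int] | None = None,
    block_size: int = 7,
    **infomax_params,
) -> GroupIcaResult:
    """Full group ICA: staged PCA, repeated Infomax, ICASSO, back-reconstruction.

    Run seeds are derived as ``seed + run_index``, so a fixed seed yields a
    bit-identical decomposition.
    """
    if stage_dims is None:
        t_min = min(s.n_timepoints for s in sessions)
        stage_dims = (min(40, t_min), min(30, t_min), n_components)
    if stage_dims[2] != n_components:
        raise ValidationError("stage_dims[2] must equal n_components")
    reduced, projections = reduce_stagewise_pca(sessions, stage_dims, block_size)
    runs = [
        infomax_ica(reduced, seed=seed + r, **infomax_params) for r in range(n_runs)
    ]
    selected, stability = icasso_select(runs, n_components, reduced=reduced)
    subject_maps, subject_tcs = back_reconstruct(selected, projections, sessions)
    logger.info(
        "group ICA: %d sessions, dims %s, %d runs, stability %s",
        len(sessions), stage_dims, n_runs, np.round(stability, 3),
    )
    return GroupIcaResult(
        group=selected,
        subject_maps=subject_maps,
        subject_timecourses=subject_tcs,
        stability=stability,
        reduction=projections,
    )
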