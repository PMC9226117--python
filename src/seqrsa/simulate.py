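"""Synthetic designs, behavior and multi-voxel patterns.

The generator emulates the statistical structure the analyses assume: four
sequences of five events with virtual times in [6, 24] virtual hours and
sequence-specific clock speeds (dissociating virtual from real time), ten
mini-blocks of patterns per scanning phase, a planted positive
within-sequence and negative across-sequence relationship between virtual
temporal distance and pattern-similarity change, and behavioral responses
with a tunable generalization bias and swap-error rate.

Similarity structure is planted in the expected correlation matrix of the
post-phase event patterns (then sampled), so downstream RSA is exercised
end to end rather than on post-hoc adjusted similarities.  All generators
are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .behavior import generalization_predictor
from .design import (
    ExperimentDesign,
    N_EVENTS,
    N_POSITIONS,
    N_SEQUENCES,
    VIRTUAL_DAY,
    build_pair_table,
    zscore,
)
from .exceptions import DesignValidationError, GenerationError
from .rsa import PatternDataset

__all__ = [
    "SimulationConfig",
    "SyntheticSubject",
    "generate_design",
    "simulate_behavior",
    "simulate_patterns",
    "simulate_dataset",
    "generate_volume_dataset",
    "nearest_psd_correlation",
    "planted_change_target",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Experiment-scale simulation settings.

    The defaults mirror the experimental conditions the analyses assume:
    28 subjects, 10 mini-blocks
    per phase, four sequences of five events on a 6-to-24 virtual-hour day
    with two distinct clock speeds.  ``a_within`` (positive) and
    ``b_across`` (negative) are the planted slopes of similarity change on
    z-scored virtual distance for same- and different-sequence pairs, in
    correlation units.  ``uniform_slope``, when set, replaces both with a
    single slope for all pairs regardless of sequence membership (the
    entorhinal-style representational format).
    """

    n_subjects: int = 28
    n_voxels: int = 100
    n_miniblocks: int = 10
    pattern_noise_sd: float = 1.0
    signal_sd: float = 1.0
    base_correlation: float = 0.1
    a_within: float = 0.04
    b_across: float = -0.04
    baseline_change: float = 0.0
    uniform_slope: float | None = None
    behavior_noise_sd: float = 1.0
    gamma_bias: float = 0.5
    clip_responses: bool = True
    p_swap: float = 0.4
    p_random_sort_error: float = 0.2
    clock_speeds: tuple[float, ...] = (0.55, 0.45, 0.55, 0.45)  # virtual h / s
    min_gap: float = 2.5  # virtual hours between successive events
    volume_dims: tuple[int, int, int] = (12, 12, 12)
    voxel_size_mm: float = 1.5
    brain_margin: int = 2
    volume_noise_sd: float = 0.35
    cluster_center: tuple[int, int, int] | None = None
    cluster_radius: int = 2
    cluster_a_within: float = 0.3
    cluster_b_across: float = -0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_swap", "p_random_sort_error"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise DesignValidationError(f"{name} must lie in [0, 1]")
        for name in ("n_subjects", "n_voxels", "n_miniblocks"):
            if getattr(self, name) <= 0:
                raise DesignValidationError(f"{name} must be positive")
        if self.n_miniblocks < 2:
            raise DesignValidationError("n_miniblocks must be at least 2")
        if len(set(self.clock_speeds)) < 2:
            raise DesignValidationError("need at least two distinct clock speeds")


@dataclass
class SyntheticSubject:
    subject_id: int
    design: ExperimentDesign
    behavior: pd.DataFrame = field(repr=False)
    patterns_pre: PatternDataset = field(repr=False)
    patterns_post: PatternDataset = field(repr=False)


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------

def generate_design(config: SimulationConfig, seed: int | None = None) -> ExperimentDesign:
    """Draw event times: 5 strictly increasing virtual times per sequence.

    Times are uniform on the virtual day subject to a minimum gap
    (rejection sampling with a bounded number of attempts); real times
    derive from virtual gaps divided by the sequence's clock speed.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    lo, hi = VIRTUAL_DAY
    if (N_POSITIONS - 1) * config.min_gap > (hi - lo):
        raise GenerationError(
            f"min_gap={config.min_gap} infeasible for {N_POSITIONS} events "
            f"in a {hi - lo}-hour window"
        )
    rows = []
    event_id = 1
    for s in range(N_SEQUENCES):
        speed = config.clock_speeds[s % len(config.clock_speeds)]
        for _ in range(10_000):
            vt = np.sort(rng.uniform(lo, hi, N_POSITIONS))
            if np.all(np.diff(vt) >= config.min_gap):
                break
        else:  # pragma: no cover - reachable only for near-infeasible gaps
            raise GenerationError("could not satisfy the minimum-gap constraint")
        rt = (vt - vt[0]) / speed
        for p in range(N_POSITIONS):
            rows.append({
                "event_id": event_id, "sequence_id": s + 1, "position": p + 1,
                "virtual_time": float(vt[p]), "real_time": float(rt[p]),
            })
            event_id += 1
    return ExperimentDesign(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# behavior
# ---------------------------------------------------------------------------

def simulate_behavior(
    design: ExperimentDesign,
    config: SimulationConfig,
    seed: int | None = None,
    subject_id: int = 1,
) -> pd.DataFrame:
    """Timeline responses with a generalization bias, plus sorted groups.

    remembered_time(e) = virtual_time(e) + gamma_bias * d(e) + noise, with
    d(e) the relative-time-of-others deviation; responses are clipped to
    the virtual day.  Sorting starts correct; with probability ``p_swap`` a
    same-position pair of events is exchanged between two sequences and
    with probability ``p_random_sort_error`` one event is moved to a
    uniformly chosen wrong group.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    ev = design.events.sort_values("event_id").reset_index(drop=True)
    pred = generalization_predictor(design)
    noise = rng.normal(0.0, config.behavior_noise_sd, N_EVENTS) \
        if config.behavior_noise_sd > 0 else np.zeros(N_EVENTS)
    remembered = (
        ev["virtual_time"].to_numpy()
        + config.gamma_bias * pred["deviation"].to_numpy()
        + noise
    )
    if config.clip_responses:
        # the timeline bounds the responses; note that truncating boundary
        # events pulls their signed errors toward the interior, a small
        # genuine bias (not an analysis artifact) — see the methods note
        remembered = np.clip(remembered, *VIRTUAL_DAY)

    groups = ev["sequence_id"].to_numpy().copy()
    if rng.random() < config.p_swap:
        s1, s2 = rng.choice(N_SEQUENCES, size=2, replace=False) + 1
        p = rng.integers(1, N_POSITIONS + 1)
        i1 = ev[(ev["sequence_id"] == s1) & (ev["position"] == p)].index[0]
        i2 = ev[(ev["sequence_id"] == s2) & (ev["position"] == p)].index[0]
        groups[i1], groups[i2] = groups[i2], groups[i1]
    if rng.random() < config.p_random_sort_error:
        i = rng.integers(N_EVENTS)
        wrong = [g for g in range(1, N_SEQUENCES + 1) if g != groups[i]]
        groups[i] = wrong[rng.integers(len(wrong))]

    return pd.DataFrame({
        "subject_id": subject_id,
        "event_id": ev["event_id"],
        "remembered_time": remembered,
        "sorted_group": groups,
    })


# ---------------------------------------------------------------------------
# patterns
# ---------------------------------------------------------------------------

def nearest_psd_correlation(matrix: np.ndarray, tol: float = 0.0) -> np.ndarray:
    """Nearest positive-semidefinite correlation matrix.

    Eigenvalues are clipped at ``tol`` (default 0) and the diagonal is
    re-normalized to 1.  Already-PSD inputs are returned unchanged up to
    numerical precision (a fixed point of the projection).
    """
    m = np.asarray(matrix, dtype=float)
    m = (m + m.T) / 2.0
    w, v = np.linalg.eigh(m)
    if w.min() >= tol:
        return m
    w = np.clip(w, tol, None)
    m2 = (v * w) @ v.T
    d = np.sqrt(np.clip(np.diag(m2), 1e-12, None))
    m2 = m2 / np.outer(d, d)
    np.fill_diagonal(m2, 1.0)
    return (m2 + m2.T) / 2.0


def planted_change_target(design: ExperimentDesign, config: SimulationConfig) -> np.ndarray:
    """Planted expected similarity-change structure (20x20, NaN diagonal).

    baseline + a_within * zvd for same-sequence pairs and
    baseline + b_across * zvd for different-sequence pairs, where the
    virtual distance is z-scored within each pair class (matching the
    analysis convention); with ``uniform_slope`` set, a single slope on the
    all-pairs z-scored distance.
    """
    pairs = build_pair_table(design)
    target = np.zeros((N_EVENTS, N_EVENTS))
    i = pairs["event_i"].to_numpy() - 1
    j = pairs["event_j"].to_numpy() - 1
    vals = np.full(len(pairs), config.baseline_change)
    if config.uniform_slope is not None:
        vals += config.uniform_slope * zscore(pairs["virtual_distance"])
    else:
        same = pairs["same_sequence"].to_numpy()
        zvd_same = zscore(pairs.loc[same, "virtual_distance"])
        zvd_diff = zscore(pairs.loc[~same, "virtual_distance"])
        vals[same] += config.a_within * zvd_same
        vals[~same] += config.b_across * zvd_diff
    target[i, j] = vals
    target[j, i] = vals
    np.fill_diagonal(target, np.nan)
    return target


def _sample_phase(
    corr: np.ndarray, config: SimulationConfig, rng: np.random.Generator,
    n_voxels: int | None = None,
) -> np.ndarray:
    """Event-mean patterns with correlation ``corr`` plus mini-block noise."""
    nv = config.n_voxels if n_voxels is None else n_voxels
    L = np.linalg.cholesky(corr + 1e-10 * np.eye(len(corr)))
    means = config.signal_sd * (L @ rng.standard_normal((N_EVENTS, nv)))
    noise = rng.normal(0.0, config.pattern_noise_sd,
                       (N_EVENTS, config.n_miniblocks, nv))
    return means[:, None, :] + noise


_CORR_CACHE: dict = {}


def _phase_correlations(
    design: ExperimentDesign, config: SimulationConfig,
    a_within: float | None = None, b_across: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    key = (
        design.events["virtual_time"].to_numpy().tobytes(),
        design.events["sequence_id"].to_numpy().tobytes(),
        config.base_correlation, config.baseline_change, config.uniform_slope,
        config.a_within if a_within is None else a_within,
        config.b_across if b_across is None else b_across,
    )
    if key not in _CORR_CACHE:
        if len(_CORR_CACHE) > 64:
            _CORR_CACHE.clear()
        _CORR_CACHE[key] = _phase_correlations_uncached(design, config, a_within, b_across)
    return _CORR_CACHE[key]


def _phase_correlations_uncached(
    design: ExperimentDesign, config: SimulationConfig,
    a_within: float | None = None, b_across: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    c0 = np.full((N_EVENTS, N_EVENTS), config.base_correlation)
    np.fill_diagonal(c0, 1.0)
    cfg = config
    if a_within is not None or b_across is not None:
        cfg = replace(config,
                      a_within=config.a_within if a_within is None else a_within,
                      b_across=config.b_across if b_across is None else b_across)
    target = planted_change_target(design, cfg)
    delta = np.nan_to_num(target, nan=0.0)
    c_post = c0 + delta
    off = c_post[~np.eye(N_EVENTS, dtype=bool)]
    if np.any(np.abs(off) >= 1.0):
        raise GenerationError(
            "planted effects produce |correlation| >= 1 "
            f"(a_within={cfg.a_within}, b_across={cfg.b_across}, "
            f"baseline={cfg.baseline_change})"
        )
    return nearest_psd_correlation(c0), nearest_psd_correlation(c_post)


def simulate_patterns(
    design: ExperimentDesign,
    config: SimulationConfig,
    seed: int | None = None,
    subject_id: int = 1,
    roi_id: str = "roi",
) -> tuple[PatternDataset, PatternDataset]:
    """Pre/post pattern datasets with the planted similarity-change structure.

    The post-phase target correlation matrix C = C0 + baseline +
    a_within*zvd*[same] + b_across*zvd*[different] is projected to the
    nearest PSD correlation matrix; event-mean patterns are drawn with that
    correlation across events and mini-block patterns add independent
    Gaussian noise.  Pre-phase patterns use the unstructured C0, so the
    expected post-minus-pre similarity change approximates the planted
    structure (attenuated by the noise-to-signal ratio).
    """
    if config.n_voxels < 20:
        raise DesignValidationError("n_voxels must be at least 20")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    c_pre, c_post = _phase_correlations(design, config)
    pre = _sample_phase(c_pre, config, rng)
    post = _sample_phase(c_post, config, rng)
    return (
        PatternDataset(subject_id, "pre", pre, roi_id),
        PatternDataset(subject_id, "post", post, roi_id),
    )


def simulate_dataset(
    config: SimulationConfig,
    seed: int | None = None,
    with_patterns: bool = True,
) -> tuple[ExperimentDesign, list[SyntheticSubject]]:
    """A full synthetic sample: one design shared by ``n_subjects`` subjects."""
    root = np.random.SeedSequence(config.seed if seed is None else seed)
    design_seed, *subject_seeds = root.spawn(config.n_subjects + 1)
    design = generate_design(config, seed=int(design_seed.generate_state(1)[0] % 2**31))
    subjects = []
    for sid, ss in enumerate(subject_seeds, start=1):
        s_beh, s_pat = ss.spawn(2)
        behavior = simulate_behavior(
            design, config, seed=int(s_beh.generate_state(1)[0] % 2**31), subject_id=sid
        )
        if with_patterns:
            pre, post = simulate_patterns(
                design, config, seed=int(s_pat.generate_state(1)[0] % 2**31),
                subject_id=sid,
            )
        else:
            pre = post = None
        subjects.append(SyntheticSubject(sid, design, behavior, pre, post))
    return design, subjects


# ---------------------------------------------------------------------------
# searchlight volumes
# ---------------------------------------------------------------------------

@dataclass
class VolumeDataset:
    """Per-subject 4D pattern volumes with masks and planted ground truth."""

    design: ExperimentDesign
    pre: list[np.ndarray] = field(repr=False)   # (E, B, X, Y, Z) per subject
    post: list[np.ndarray] = field(repr=False)
    brain_mask: np.ndarray = field(repr=False)
    graymatter_mask: np.ndarray = field(repr=False)
    #: a-priori small-volume-correction region, nested strictly inside the
    #: brain mask so its edge voxels are not smoothing-boundary voxels
    svc_mask: np.ndarray | None = field(default=None, repr=False)
    cluster_mask: np.ndarray | None = field(default=None, repr=False)
    cluster_center: tuple[int, int, int] | None = None
    voxel_size_mm: float = 1.5


def _box_mask(dims: tuple[int, int, int], margin: int) -> np.ndarray:
    mask = np.zeros(dims, dtype=bool)
    sl = tuple(slice(margin, d - margin) for d in dims)
    mask[sl] = True
    return mask


def generate_volume_dataset(
    config: SimulationConfig,
    seed: int | None = None,
    n_subjects: int | None = None,
    null: bool = False,
) -> VolumeDataset:
    """Toy searchlight volumes with one planted cluster.

    Voxels inside the cluster (a lattice sphere of ``cluster_radius``
    around ``cluster_center``) carry the planted similarity-change
    structure at the stronger ``cluster_a_within``/``cluster_b_across``
    slopes; voxels outside carry null structure.  The brain mask is a box
    inset by ``brain_margin`` voxels, the gray-matter mask equals the brain
    mask (nested by construction).  With ``null=True`` the cluster also
    carries null structure, for specificity checks.
    """
    dims = tuple(config.volume_dims)
    if any(d < 12 for d in dims):
        raise DesignValidationError("volume_dims must be at least 12 per axis")
    center = config.cluster_center or tuple(d // 2 for d in dims)
    if any(not 0 <= c < d for c, d in zip(center, dims)):
        raise DesignValidationError(f"cluster center {center} outside volume {dims}")
    config = replace(config, pattern_noise_sd=config.volume_noise_sd)
    root = np.random.SeedSequence(config.seed if seed is None else seed)
    design_seed, *subject_seeds = root.spawn(
        (config.n_subjects if n_subjects is None else n_subjects) + 1
    )
    design = generate_design(config, seed=int(design_seed.generate_state(1)[0] % 2**31))

    brain = _box_mask(dims, config.brain_margin)
    gray = brain.copy()
    grid = np.indices(dims)
    dist2 = sum((g - c) ** 2 for g, c in zip(grid, center))
    cluster = (dist2 <= config.cluster_radius ** 2) & brain
    n_in = int(cluster.sum())
    n_out = int(brain.sum() - n_in)

    # graded cluster: the planted effect is strongest at the center voxel and
    # falls off linearly with distance, so the group peak localizes there
    shells = sorted(set(dist2[cluster].tolist()))
    shell_corrs = []
    for d2 in shells:
        w = max(0.0, 1.0 - np.sqrt(d2) / (config.cluster_radius + 1.0))
        c_pre, c_post = _phase_correlations(
            design, config,
            a_within=0.0 if null else w * config.cluster_a_within,
            b_across=0.0 if null else w * config.cluster_b_across,
        )
        shell_corrs.append((d2, c_pre, c_post))
    c_null, _ = _phase_correlations(design, config, a_within=0.0, b_across=0.0)
    E, B = N_EVENTS, config.n_miniblocks
    pre_list, post_list = [], []
    outside = brain & ~cluster
    for ss in subject_seeds:
        rng = np.random.default_rng(ss.generate_state(1)[0] % 2**31)
        pre_vol = np.zeros((E, B) + dims, dtype=np.float32)
        post_vol = np.zeros((E, B) + dims, dtype=np.float32)
        for d2, c_pre, c_post in shell_corrs:
            shell = cluster & (dist2 == d2)
            k = int(shell.sum())
            pre_vol[:, :, shell] = _sample_phase(c_pre, config, rng, n_voxels=k)
            post_vol[:, :, shell] = _sample_phase(c_post, config, rng, n_voxels=k)
        pre_vol[:, :, outside] = _sample_phase(c_null, config, rng, n_voxels=n_out)
        post_vol[:, :, outside] = _sample_phase(c_null, config, rng, n_voxels=n_out)
        pre_list.append(pre_vol)
        post_list.append(post_vol)
    return VolumeDataset(
        design=design, pre=pre_list, post=post_list,
        brain_mask=brain, graymatter_mask=gray,
        svc_mask=_box_mask(dims, config.brain_margin + 1),
        cluster_mask=cluster, cluster_center=center,
        voxel_size_mm=config.voxel_size_mm,
    )
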