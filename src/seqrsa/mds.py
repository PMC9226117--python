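"""Model-derived distances, non-metric MDS and the stress permutation test.

To visualize how the sequences may be arranged in a low-dimensional
representational space, similarity values predicted from the fixed effects
of the mixed model (virtual-time x sequence-membership) are converted to
distances (max-similarity minus similarity) and embedded with non-metric
MDS (SMACOF with isotonic disparities, many random starts, lowest stress-1
kept).  The observed stress is tested against a null distribution from
permuting the off-diagonal input distances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import isotonic_regression
from scipy.spatial.distance import pdist, squareform

from .design import N_EVENTS
from .exceptions import DesignValidationError

__all__ = [
    "EmbeddingResult",
    "model_predicted_distances",
    "nonmetric_mds",
    "stress_permutation_test",
    "embedding_diagnostics",
]


@dataclass
class EmbeddingResult:
    """Best-of-n-starts 2-D configuration with its normalized stress-1."""

    configuration: np.ndarray
    stress: float
    n_starts: int
    seed: int | None
    degenerate: bool = False


def _check_distance_matrix(d: np.ndarray) -> np.ndarray:
    d = np.asarray(d, float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise DesignValidationError("distance matrix must be square")
    if not np.allclose(d, d.T, equal_nan=True):
        raise DesignValidationError("distance matrix must be symmetric")
    if np.any(np.nan_to_num(d) < 0):
        raise DesignValidationError("distances must be nonnegative")
    d = d.copy()
    np.fill_diagonal(d, 0.0)
    return d


def model_predicted_distances(
    fitted, pairs: pd.DataFrame, fe_terms: dict[str, str] | None = None
) -> np.ndarray:
    """Distances from fixed-effect-predicted similarities, max-minus rule.

    ``fitted`` is a MixedModelComparison (or any object with ``fe_params``
    and the membership x virtual-time fixed effects).  Predicted similarity
    per pair uses the fixed effects only; distances are
    d_ij = max_kl(sim_kl) - sim_ij, giving a zero diagonal and distance 0
    for the most similar pair.
    """
    fe = dict(getattr(fitted, "fe_params"))
    sim = _predict_similarity(fe, pairs)
    if not np.all(np.isfinite(sim)):
        raise DesignValidationError("non-finite model-predicted similarities")
    d = np.zeros((N_EVENTS, N_EVENTS))
    i = pairs["event_i"].to_numpy() - 1
    j = pairs["event_j"].to_numpy() - 1
    dist = sim.max() - sim
    d[i, j] = dist
    d[j, i] = dist
    return d


def _predict_similarity(fe: dict[str, float], pairs: pd.DataFrame) -> np.ndarray:
    """Evaluate intercept + vt + membership + vt:membership fixed effects."""
    from .design import zscore
    from .inference import deviation_code

    vt = zscore(pairs["virtual_distance"])
    mem = deviation_code(pairs["same_sequence"], levels=(True, False))
    cols = {"Intercept": np.ones(len(pairs)), "vt": vt, "mem": mem, "vt_mem": vt * mem}
    sim = np.zeros(len(pairs))
    used = []
    for name, value in fe.items():
        if name in cols:
            sim += value * cols[name]
            used.append(name)
    if "vt_mem" not in used:
        raise DesignValidationError(
            "fitted model must include the membership x virtual-time interaction"
        )
    return sim


def _smacof_single(
    d_cond: np.ndarray,
    order: np.ndarray,
    inv_order: np.ndarray,
    X: np.ndarray,
    max_iter: int,
    eps: float,
    trace: list | None = None,
) -> tuple[np.ndarray, float]:
    """One SMACOF start: majorization with isotonic disparities.

    ``d_cond`` are the condensed input distances, ``order`` sorts them
    ascending (ties kept in a fixed arbitrary order).  Returns the
    configuration and its stress-1.  The majorization step never increases
    raw stress; iteration stops when the stress-1 decrease is below ``eps``.
    """
    n = X.shape[0]
    prev = np.inf
    stress1 = np.inf
    for _ in range(max_iter):
        delta = pdist(X)
        delta = np.maximum(delta, 1e-12)
        # monotone regression of embedded distances on the input order
        dhat = isotonic_regression(delta[order]).x[inv_order]
        # normalize disparities to the scale of the embedded distances
        dhat = dhat * np.sqrt((delta ** 2).sum() / (dhat ** 2).sum())
        stress1 = np.sqrt(((dhat - delta) ** 2).sum() / (delta ** 2).sum())
        if trace is not None:
            trace.append(stress1)
        if prev - stress1 < eps:
            break
        prev = stress1
        # Guttman transform
        ratio = squareform(dhat / delta)
        B = -ratio
        np.fill_diagonal(B, ratio.sum(axis=1))
        X = (B @ X) / n
    return X, float(stress1)


def nonmetric_mds(
    distances: np.ndarray,
    ndim: int = 2,
    n_starts: int = 1000,
    seed: int | None = None,
    max_iter: int = 300,
    eps: float = 1e-6,
    trace: list | None = None,
) -> EmbeddingResult:
    """Non-metric MDS: best configuration over random starts.

    SMACOF majorization with monotone (isotonic) disparity regression;
    every start begins from a random configuration and iterates until the
    stress-1 decrease falls below ``eps`` or ``max_iter`` iterations; the
    lowest-stress-1 configuration is kept and centered at the origin.
    """
    d = _check_distance_matrix(distances)
    n = len(d)
    d_cond = squareform(d, checks=False)
    if np.all(d_cond == 0):
        return EmbeddingResult(np.zeros((n, ndim)), 0.0, n_starts, seed,
                               degenerate=True)
    order = np.argsort(d_cond, kind="stable")
    inv_order = np.empty_like(order)
    inv_order[order] = np.arange(len(order))
    rng = np.random.default_rng(seed)
    best: tuple[np.ndarray, float] | None = None
    scale = d_cond.max()
    for _ in range(n_starts):
        X0 = rng.uniform(-scale, scale, (n, ndim))
        X, stress = _smacof_single(d_cond, order, inv_order, X0, max_iter, eps,
                                   trace=trace)
        if best is None or stress < best[1]:
            best = (X, stress)
    config = best[0] - best[0].mean(axis=0, keepdims=True)
    return EmbeddingResult(config, best[1], n_starts, seed)


def _permute_offdiagonal(d: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    n = len(d)
    iu = np.triu_indices(n, k=1)
    vals = d[iu].copy()
    rng.shuffle(vals)
    out = np.zeros_like(d)
    out[iu] = vals
    return out + out.T


def stress_permutation_test(
    distances: np.ndarray,
    n_iter: int = 1000,
    seed: int | None = None,
    n_starts_null: int = 10,
    ndim: int = 2,
) -> dict:
    """Stress of the observed embedding vs permuted-distance embeddings.

    Each iteration shuffles the off-diagonal distances (as a set,
    preserving symmetry), re-embeds with ``n_starts_null`` random starts,
    and records the stress.  p is the (add-one) proportion of null
    stresses at or below the observed stress; z standardizes the observed
    stress by the null mean and sd (structured inputs give z < 0).
    """
    d = _check_distance_matrix(distances)
    offdiag = d[np.triu_indices(len(d), k=1)]
    if np.all(offdiag == offdiag[0]):
        # permuting a constant matrix cannot move the stress: flag, no z
        return {"degenerate": True, "z": np.nan, "p": np.nan, "stress": np.nan}
    meta = {}
    if n_iter < 100:
        meta["warning"] = f"n_iter={n_iter} is low; permutation p unstable"
    rng = np.random.default_rng(seed)
    observed = nonmetric_mds(d, ndim=ndim, n_starts=max(n_starts_null, 10),
                             seed=int(rng.integers(2**31 - 1)))
    if observed.degenerate:
        return {"degenerate": True, "z": np.nan, "p": np.nan, "stress": 0.0}
    null = np.empty(n_iter)
    for i in range(n_iter):
        perm = _permute_offdiagonal(d, rng)
        null[i] = nonmetric_mds(perm, ndim=ndim, n_starts=n_starts_null,
                                seed=int(rng.integers(2**31 - 1))).stress
    sd = null.std()
    if sd == 0:
        return {"degenerate": True, "z": np.nan, "p": np.nan,
                "stress": observed.stress}
    z = (observed.stress - null.mean()) / sd
    p = (1.0 + np.sum(null <= observed.stress)) / (1.0 + n_iter)
    return {"degenerate": False, "stress": observed.stress, "z": float(z),
            "p": float(p), "null_mean": float(null.mean()), "null_sd": float(sd),
            "n_iter": n_iter, "embedding": observed, **meta}


def embedding_diagnostics(embedding: EmbeddingResult, distances: np.ndarray) -> dict:
    """Median-split contrast and rank correlation of input vs embedded distances."""
    d = _check_distance_matrix(distances)
    iu = np.triu_indices(len(d), k=1)
    din = d[iu]
    config = embedding.configuration
    demb = np.sqrt(((config[:, None, :] - config[None, :, :]) ** 2).sum(-1))[iu]
    med = np.median(din)
    low = din <= med
    if not (~low).any():
        t_stat, t_p = np.nan, np.nan
    else:
        t_stat, t_p = stats.ttest_ind(demb[~low], demb[low])
    rho, rho_p = stats.spearmanr(din, demb)
    return {
        "high_mean": float(demb[~low].mean()) if (~low).any() else np.nan,
        "low_mean": float(demb[low].mean()),
        "t": float(t_stat), "t_p": float(t_p),
        "spearman_rho": float(rho), "spearman_p": float(rho_p),
    }


def embedding_to_csv(embedding: EmbeddingResult, path) -> None:
    df = pd.DataFrame(embedding.configuration, columns=["dim1", "dim2"])
    df.insert(0, "event_id", np.arange(1, len(df) + 1))
    df.to_csv(path, index=False)
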