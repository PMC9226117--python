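"""Cross-mini-block pattern similarity and pre-to-post similarity change.

Pattern similarity between two events is the mean Fisher-z-transformed
Pearson correlation of their multi-voxel patterns across all pairs of
*different* mini-blocks (same-mini-block comparisons are excluded, removing
within-block dependencies).  The core dependent measure of the package is
the change of this quantity from the pre-learning to the post-learning
scanning phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import N_EVENTS, select_pairs
from .exceptions import DesignValidationError, PhaseMismatchError

#: correlations are clipped to +/- (1 - FISHER_CLIP) before atanh so that
#: identical patterns yield a large finite z rather than +inf
FISHER_CLIP = 1e-7


@dataclass
class PatternDataset:
    """Event x mini-block x voxel activation patterns for one phase.

    ``patterns`` has shape (n_events, n_miniblocks, n_voxels).
    """

    subject_id: int
    phase: str  # "pre" | "post"
    patterns: np.ndarray = field(repr=False)
    roi_id: str = "roi"

    def __post_init__(self) -> None:
        if self.phase not in ("pre", "post"):
            raise PhaseMismatchError(f"phase must be 'pre' or 'post', got {self.phase!r}")
        p = np.asarray(self.patterns, dtype=float)
        if p.ndim != 3:
            raise DesignValidationError("patterns must be (events, mini-blocks, voxels)")
        self.patterns = p

    @property
    def n_miniblocks(self) -> int:
        return self.patterns.shape[1]

    @property
    def n_voxels(self) -> int:
        return self.patterns.shape[2]


def fisher_z(r: np.ndarray | float) -> np.ndarray:
    """Fisher z-transform with clipping at +/-(1 - 1e-7)."""
    return np.arctanh(np.clip(r, -1 + FISHER_CLIP, 1 - FISHER_CLIP))


def _cross_block_mean_z(flat_corr: np.ndarray, n_events: int, n_blocks: int) -> np.ndarray:
    """Average Fisher-z correlations over ordered cross-block pairs.

    ``flat_corr`` is the (E*B, E*B) correlation matrix of patterns stacked
    event-major.  Returns an (E, E) matrix with NaN on the diagonal.
    """
    z = fisher_z(flat_corr).reshape(n_events, n_blocks, n_events, n_blocks)
    block_ok = ~np.eye(n_blocks, dtype=bool)  # a != b
    # mean over the n_blocks*(n_blocks-1) ordered cross-block pairs
    mask = block_ok[None, :, None, :]
    sums = np.where(mask, z, 0.0).sum(axis=(1, 3))
    out = sums / block_ok.sum()
    np.fill_diagonal(out, np.nan)
    return out


def pairwise_similarity(patterns: PatternDataset | np.ndarray) -> np.ndarray:
    """Mean Fisher-z Pearson similarity for every pair of events.

    For events i != j the Pearson correlation between the pattern of i in
    mini-block a and the pattern of j in mini-block b is computed for every
    ordered block pair a != b (90 correlations at 10 blocks), Fisher
    z-transformed, and averaged.  The result is symmetric by construction
    because ordered pairs cover both directions; the diagonal is NaN.
    """
    arr = patterns.patterns if isinstance(patterns, PatternDataset) else np.asarray(patterns, float)
    n_events, n_blocks, n_voxels = arr.shape
    if n_blocks < 2:
        raise DesignValidationError("need at least 2 mini-blocks for cross-block similarity")
    flat = arr.reshape(n_events * n_blocks, n_voxels)
    sd = flat.std(axis=1)
    if np.any(sd == 0):
        k = int(np.argmax(sd == 0))
        raise DesignValidationError(
            f"zero-variance pattern vector at event {k // n_blocks + 1}, "
            f"block {k % n_blocks + 1}"
        )
    corr = np.corrcoef(flat)
    return _cross_block_mean_z(corr, n_events, n_blocks)


def similarity_change(pre: np.ndarray, post: np.ndarray) -> np.ndarray:
    """Post-minus-pre similarity: the pattern-similarity-change matrix."""
    pre = np.asarray(pre, float)
    post = np.asarray(post, float)
    if pre.shape != post.shape:
        raise DesignValidationError("pre and post similarity matrices differ in shape")
    return post - pre


def similarity_change_from_datasets(pre: PatternDataset, post: PatternDataset) -> np.ndarray:
    if pre.phase != "pre" or post.phase != "post":
        raise PhaseMismatchError(
            f"expected phases ('pre', 'post'), got ({pre.phase!r}, {post.phase!r})"
        )
    if pre.roi_id != post.roi_id:
        raise PhaseMismatchError("pre and post datasets are from different ROIs")
    return similarity_change(pairwise_similarity(pre), pairwise_similarity(post))


def pair_values(matrix: np.ndarray, pairs: pd.DataFrame) -> np.ndarray:
    """Extract the per-pair entries of a 20x20 matrix in pair-table order."""
    i = pairs["event_i"].to_numpy() - 1
    j = pairs["event_j"].to_numpy() - 1
    return np.asarray(matrix, float)[i, j]


def median_split_summary(
    change: np.ndarray, pairs: pd.DataFrame, subset: str = "same"
) -> dict[str, float]:
    """Mean similarity change for low vs high virtual-distance halves.

    Pairs at or below the median virtual distance of the subset form the
    "low" half, pairs strictly above it the "high" half.  Descriptive only.
    """
    sel = select_pairs(pairs, subset)
    if len(sel) == 0:
        raise DesignValidationError("empty pair subset")
    vals = pair_values(change, sel)
    dist = sel["virtual_distance"].to_numpy(float)
    med = np.median(dist)
    low = dist <= med
    return {
        "low": float(vals[low].mean()),
        "high": float(vals[~low].mean()) if (~low).any() else float("nan"),
        "median": float(med),
    }


def similarity_to_tsv(matrix: np.ndarray, path) -> None:
    """Write a 20x20 similarity(-change) matrix as TSV with event_id labels."""
    ids = list(range(1, N_EVENTS + 1))
    pd.DataFrame(matrix, index=ids, columns=ids).to_csv(path, sep="\t")


def similarity_from_tsv(path) -> np.ndarray:
    return pd.read_csv(path, sep="\t", index_col=0).to_numpy(float)
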