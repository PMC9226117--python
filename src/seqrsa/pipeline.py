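"""ROI analyses: subset models, residual test, interaction, region contrast.

Wires the pair table, similarity-change matrices and the two-level
permutation machinery into the region-of-interest analyses: virtual-time
models on same-sequence and different-sequence pairs (with optional order,
real-time and first/last control predictors), the residual virtual-time
test, the sequence-membership interaction (summary-statistics and
mixed-model paths), and the hippocampus-vs-entorhinal region contrast.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import select_pairs, zscore
from .exceptions import DesignValidationError
from .inference import (
    GroupTestResult,
    MixedModelComparison,
    SubjectModelResult,
    deviation_code,
    fit_mixed_and_lrt,
    group_signflip_test,
    permutation_rm_anova,
    permutation_z,
)
from .rsa import pair_values

__all__ = [
    "RoiAnalysisSpec",
    "RoiSimilarityModel",
    "RoiSimilarityResults",
    "run_roi_model",
    "residual_virtual_time_test",
    "sequence_interaction_test",
    "region_contrast",
    "build_long_table",
]

PREDICTOR_COLUMNS = {
    "virtual": "virtual_distance",
    "order": "order_distance",
    "real": "real_distance",
    "first_last": "first_last",
}


@dataclass(frozen=True)
class RoiAnalysisSpec:
    """One ROI model: pair subset, predictors, focal predictor, resampling."""

    roi_id: str = "roi"
    subset: str = "same"  # same | different | all
    predictors: tuple[str, ...] = ("virtual",)
    focal: str = "virtual"
    n_perm: int = 10_000
    n_flips: int = 10_000
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.focal not in self.predictors:
            raise DesignValidationError("focal predictor must be among the predictors")
        unknown = set(self.predictors) - set(PREDICTOR_COLUMNS)
        if unknown:
            raise DesignValidationError(f"unknown predictors {sorted(unknown)}")
        if "first_last" in self.predictors and self.subset == "different":
            raise DesignValidationError(
                "first_last applies to same-sequence pairs only"
            )


def _predictor_frame(pairs: pd.DataFrame, spec: RoiAnalysisSpec) -> pd.DataFrame:
    """Z-scored predictors over the analyzed subset (flags deviation-coded)."""
    sel = select_pairs(pairs, spec.subset)
    if len(sel) == 0:
        raise DesignValidationError(f"empty pair subset {spec.subset!r}")
    X = {}
    for name in spec.predictors:
        col = PREDICTOR_COLUMNS[name]
        if name == "first_last":
            X[name] = deviation_code(sel[col], levels=(True, False))
        else:
            X[name] = zscore(sel[col])
    return pd.DataFrame(X, index=sel.index)


@dataclass
class RoiSimilarityResults:
    """Per-subject permutation Z-values and the group sign-flip test."""

    spec: RoiAnalysisSpec
    subject_results: list[SubjectModelResult]
    group: GroupTestResult

    @property
    def subject_z(self) -> np.ndarray:
        return np.array([r.zvalues[self.spec.focal] for r in self.subject_results])

    def summary(self) -> str:
        z = self.subject_z
        lines = [
            f"ROI similarity-change model [{self.spec.roi_id}]",
            f"  subset={self.spec.subset}, predictors={list(self.spec.predictors)}, "
            f"focal={self.spec.focal}",
            f"  n={len(z)} subjects, mean Z={z.mean():.3f}",
            "  group " + self.group.summary(),
        ]
        return "\n".join(lines)


class RoiSimilarityModel:
    """Similarity change regressed on time metrics within a pair subset.

    statsmodels-style entry point: construct from the per-subject
    similarity-change matrices (n_subjects, 20, 20) and the pair table,
    then ``fit()`` to obtain per-subject permutation Z-values and the
    group-level sign-flip test.
    """

    def __init__(self, changes: np.ndarray, pairs: pd.DataFrame, spec: RoiAnalysisSpec):
        self.changes = np.asarray(changes, float)
        self.pairs = pairs
        self.spec = spec

    def fit(self) -> RoiSimilarityResults:
        spec = self.spec
        sel = select_pairs(self.pairs, spec.subset)
        X = _predictor_frame(self.pairs, spec)
        rng = np.random.default_rng(spec.seed)
        subject_results = []
        for change in self.changes:
            y = pair_values(change, sel)
            subject_results.append(
                permutation_z(y, X, focal=(spec.focal,), n_perm=spec.n_perm,
                              seed=int(rng.integers(2**31 - 1)))
            )
        z = np.array([r.zvalues[spec.focal] for r in subject_results])
        group = group_signflip_test(z, n_flips=spec.n_flips,
                                    seed=int(rng.integers(2**31 - 1)))
        return RoiSimilarityResults(spec, subject_results, group)


def run_roi_model(
    changes: np.ndarray, pairs: pd.DataFrame, spec: RoiAnalysisSpec
) -> RoiSimilarityResults:
    """Functional form of :class:`RoiSimilarityModel`."""
    return RoiSimilarityModel(changes, pairs, spec).fit()


def residual_virtual_time_test(
    changes: np.ndarray,
    pairs: pd.DataFrame,
    n_perm: int = 10_000,
    seed: int | None = None,
    n_flips: int = 10_000,
    subset: str = "same",
) -> RoiSimilarityResults:
    """Virtual time explains what order and real time leave behind.

    Per subject, similarity change (same-sequence pairs) is regressed on
    order and real-time distances; the residuals are then regressed on
    virtual-time distance with the usual permutation Z, and the Z-values
    enter a group sign-flip test.
    """
    sel = select_pairs(pairs, subset)
    ctrl = pd.DataFrame({
        "order": zscore(sel["order_distance"]),
        "real": zscore(sel["real_distance"]),
    }, index=sel.index)
    Xc = np.column_stack([np.ones(len(sel)), ctrl["order"], ctrl["real"]])
    focal = pd.DataFrame({"virtual": zscore(sel["virtual_distance"])}, index=sel.index)
    rng = np.random.default_rng(seed)
    subject_results = []
    for change in changes:
        y = pair_values(change, sel)
        beta, *_ = np.linalg.lstsq(Xc, y, rcond=None)
        resid = y - Xc @ beta
        subject_results.append(
            permutation_z(resid, focal, focal=("virtual",), n_perm=n_perm,
                          seed=int(rng.integers(2**31 - 1)))
        )
    z = np.array([r.zvalues["virtual"] for r in subject_results])
    group = group_signflip_test(z, n_flips=n_flips, seed=int(rng.integers(2**31 - 1)))
    spec = RoiAnalysisSpec(subset=subset, predictors=("virtual",), focal="virtual",
                           n_perm=n_perm, n_flips=n_flips, seed=seed)
    return RoiSimilarityResults(spec, subject_results, group)


# ---------------------------------------------------------------------------
# long-format construction and interaction analyses
# ---------------------------------------------------------------------------

def build_long_table(
    changes: np.ndarray,
    pairs: pd.DataFrame,
    roi_id: str = "roi",
    include_controls: bool = False,
) -> pd.DataFrame:
    """Long-format table for mixed models: one row per subject x pair.

    Continuous metrics are z-scored over all pairs (within participant,
    identical across subjects sharing a design); sequence membership is
    deviation-coded (+0.5 same, -0.5 different); interaction columns are
    explicit products so that likelihood-ratio nesting is unambiguous.
    """
    vt = zscore(pairs["virtual_distance"])
    mem = deviation_code(pairs["same_sequence"], levels=(True, False))
    base = pd.DataFrame({
        "vt": vt, "mem": mem, "vt_mem": vt * mem,
        "event_i": pairs["event_i"].to_numpy(),
        "event_j": pairs["event_j"].to_numpy(),
    })
    if include_controls:
        base["order"] = zscore(pairs["order_distance"])
        base["real"] = zscore(pairs["real_distance"])
        base["order_mem"] = base["order"] * mem
        base["real_mem"] = base["real"] * mem
    frames = []
    for s, change in enumerate(changes, start=1):
        f = base.copy()
        f.insert(0, "subject", s)
        f["change"] = pair_values(change, pairs)
        f["roi"] = roi_id
        frames.append(f)
    return pd.concat(frames, ignore_index=True)


@dataclass
class InteractionTestResult:
    """Summary-statistics and mixed-model views of the membership interaction."""

    paired_group: GroupTestResult
    z_same: np.ndarray
    z_different: np.ndarray
    mixed: MixedModelComparison

    def summary(self) -> str:
        return (
            "sequence-membership x virtual-time interaction\n"
            f"  paired sign-flip: {self.paired_group.summary()}\n"
            f"  mixed model: {self.mixed.summary()}"
        )


def sequence_interaction_test(
    changes: np.ndarray,
    pairs: pd.DataFrame,
    n_perm: int = 10_000,
    seed: int | None = None,
    n_flips: int = 10_000,
    include_time_controls: bool = False,
) -> InteractionTestResult:
    """Does the virtual-time effect differ between pair classes?

    Summary path: sign-flip test of the paired difference between
    same-sequence and different-sequence focal Z-values.  Mixed path:
    likelihood-ratio test of the membership x virtual-time interaction,
    optionally controlling for membership x order and membership x
    real-time interactions.
    """
    rng = np.random.default_rng(seed)
    res_same = run_roi_model(changes, pairs, RoiAnalysisSpec(
        subset="same", predictors=("virtual",), focal="virtual",
        n_perm=n_perm, n_flips=n_flips, seed=int(rng.integers(2**31 - 1))))
    res_diff = run_roi_model(changes, pairs, RoiAnalysisSpec(
        subset="different", predictors=("virtual",), focal="virtual",
        n_perm=n_perm, n_flips=n_flips, seed=int(rng.integers(2**31 - 1))))
    paired = group_signflip_test(res_same.subject_z, n_flips=n_flips,
                                 seed=int(rng.integers(2**31 - 1)),
                                 paired_with=res_diff.subject_z)
    long = build_long_table(changes, pairs, include_controls=include_time_controls)
    rhs = "vt + mem + vt_mem"
    if include_time_controls:
        rhs += " + order + real + order_mem + real_mem"
    mixed = fit_mixed_and_lrt(long, f"change ~ {rhs}", focal="vt_mem",
                              re_ladder=("1 + vt_mem", "0 + vt_mem"))
    return InteractionTestResult(paired, res_same.subject_z, res_diff.subject_z, mixed)


@dataclass
class RegionContrastResult:
    """Region x membership ANOVA plus the three-way mixed-model comparison."""

    anova: dict[str, GroupTestResult]
    mixed: MixedModelComparison
    cell_z: pd.DataFrame

    def summary(self) -> str:
        lines = ["region x sequence-membership contrast"]
        for name, res in self.anova.items():
            lines.append(f"  {name}: {res.summary()}")
        lines.append(f"  mixed model: {self.mixed.summary()}")
        return "\n".join(lines)


def region_contrast(
    changes_by_roi: dict[str, np.ndarray],
    pairs: pd.DataFrame,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> RegionContrastResult:
    """Do the two regions represent sequence membership differently?

    2x2 (region x membership) permutation repeated-measures ANOVA on the
    per-subject focal Z-values, and a mixed model with the three-way
    virtual-time x membership x region interaction as the focal effect.
    """
    if len(changes_by_roi) != 2:
        raise DesignValidationError("region contrast needs exactly two ROIs")
    (roi_a, ch_a), (roi_b, ch_b) = changes_by_roi.items()
    if len(ch_a) != len(ch_b):
        raise DesignValidationError("subject mismatch between ROIs")
    rng = np.random.default_rng(seed)
    rows = []
    for roi, changes in ((roi_a, ch_a), (roi_b, ch_b)):
        for subset in ("same", "different"):
            res = run_roi_model(changes, pairs, RoiAnalysisSpec(
                roi_id=roi, subset=subset, predictors=("virtual",), focal="virtual",
                n_perm=n_perm, n_flips=1000, seed=int(rng.integers(2**31 - 1))))
            for s, z in enumerate(res.subject_z, start=1):
                rows.append({"subject": s, "region": roi, "membership": subset, "z": z})
    cell_z = pd.DataFrame(rows)
    anova = permutation_rm_anova(cell_z, dv="z", within=("region", "membership"),
                                 subject="subject", n_perm=n_perm,
                                 seed=int(rng.integers(2**31 - 1)))

    long_a = build_long_table(ch_a, pairs, roi_id=roi_a)
    long_b = build_long_table(ch_b, pairs, roi_id=roi_b)
    long = pd.concat([long_a, long_b], ignore_index=True)
    long["region_dev"] = deviation_code(long["roi"], levels=(roi_a, roi_b))
    long["vt_reg"] = long["vt"] * long["region_dev"]
    long["mem_reg"] = long["mem"] * long["region_dev"]
    long["vt_mem_reg"] = long["vt_mem"] * long["region_dev"]
    mixed = fit_mixed_and_lrt(
        long,
        "change ~ vt + mem + region_dev + vt_mem + vt_reg + mem_reg + vt_mem_reg",
        focal="vt_mem_reg",
        re_ladder=("1 + vt_mem_reg", "0 + vt_mem_reg"),
    )
    return RegionContrastResult(anova, mixed, cell_z)
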