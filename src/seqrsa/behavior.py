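"""Timeline, sorting, swap-error and generalization-bias analyses.

Memory for the sequences is probed with two tasks.  In the timeline task
participants place the five events of each sequence on a 6 a.m.-midnight
timeline; remembered times are regressed on virtual time with order and
real time as control predictors, using the two-level permutation scheme.
In the sorting task all 20 events are grouped into four sets; accuracy is
scored under the group-to-sequence assignment maximizing overlap, and swap
errors (same-position events interchanged between sequences) are tested
against a surrogate null of random sorting errors.

The generalization bias asks whether the constructed time of an event is
pulled toward the mean time of the events at the same sequence position in
the other three sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import linear_sum_assignment

from .design import (
    ExperimentDesign,
    N_POSITIONS,
    N_SEQUENCES,
    zscore,
)
from .exceptions import DegeneratePredictorError, DesignValidationError
from .inference import GroupTestResult, SubjectModelResult, group_signflip_test, permutation_z

BEHAVIOR_COLUMNS = ["subject_id", "event_id", "remembered_time", "sorted_group"]


# ---------------------------------------------------------------------------
# generalization predictor
# ---------------------------------------------------------------------------

def generalization_predictor(design: ExperimentDesign) -> pd.DataFrame:
    """Per event: mean virtual time of same-position events elsewhere.

    ``other_mean_time`` averages the virtual times of the three events at
    the same sequence position in the other sequences; ``deviation`` is
    other_mean_time minus the event's own virtual time.  A positive
    regression of signed construction errors on this deviation is the
    generalization bias.
    """
    ev = design.events
    rows = []
    for _, e in ev.iterrows():
        others = ev[(ev["position"] == e["position"]) & (ev["sequence_id"] != e["sequence_id"])]
        m = others["virtual_time"].mean()
        rows.append({
            "event_id": int(e["event_id"]),
            "other_mean_time": float(m),
            "deviation": float(m - e["virtual_time"]),
        })
    return pd.DataFrame(rows).sort_values("event_id").reset_index(drop=True)


def signed_errors(behavior: pd.DataFrame, design: ExperimentDesign) -> pd.DataFrame:
    """Attach signed_error = remembered_time - virtual_time per response."""
    merged = behavior.merge(
        design.events[["event_id", "virtual_time", "sequence_id", "position"]],
        on="event_id", validate="many_to_one",
    )
    merged["signed_error"] = merged["remembered_time"] - merged["virtual_time"]
    return merged


# ---------------------------------------------------------------------------
# timeline task
# ---------------------------------------------------------------------------

@dataclass
class SubjectGroupAnalysis:
    """Per-subject model results plus the group-level sign-flip test."""

    subject_results: dict[int, SubjectModelResult]
    focal: str
    group: GroupTestResult
    meta: dict = field(default_factory=dict)

    @property
    def subject_z(self) -> pd.Series:
        return pd.Series({s: r.zvalues[self.focal] for s, r in self.subject_results.items()},
                         name=f"z_{self.focal}")

    @property
    def subject_coef(self) -> pd.Series:
        return pd.Series({s: r.coef[self.focal] for s, r in self.subject_results.items()},
                         name=f"coef_{self.focal}")

    def summary(self) -> str:
        z = self.subject_z
        return (f"focal={self.focal}: mean Z={z.mean():.3f} over n={len(z)} subjects; "
                + self.group.summary())


def timeline_regression(
    behavior: pd.DataFrame,
    design: ExperimentDesign,
    n_perm: int = 10_000,
    seed: int | None = None,
    n_flips: int = 10_000,
) -> SubjectGroupAnalysis:
    """Remembered times regressed on virtual time, order and real time.

    Per subject: OLS of the 20 remembered times on the three z-scored time
    metrics with intercept; each coefficient's t is converted to a
    permutation Z by shuffling the outcome.  Group level: sign-flip test of
    the virtual-time Z-values against zero.
    """
    ev = design.events.sort_values("event_id")
    X = pd.DataFrame({
        "virtual_time": zscore(ev["virtual_time"]),
        "order": zscore(ev["position"]),
        "real_time": zscore(ev["real_time"]),
    })
    rng = np.random.default_rng(seed)
    results: dict[int, SubjectModelResult] = {}
    for subject, grp in behavior.groupby("subject_id"):
        grp = grp.sort_values("event_id")
        if len(grp) != len(ev):
            raise DesignValidationError(
                f"subject {subject}: expected {len(ev)} responses, got {len(grp)}"
            )
        y = grp["remembered_time"].to_numpy(float)
        if len(np.unique(y)) < 4:
            raise DegeneratePredictorError(
                f"subject {subject}: fewer than 4 distinct responses"
            )
        results[int(subject)] = permutation_z(
            y, X, focal=("virtual_time", "order", "real_time"),
            n_perm=n_perm, seed=int(rng.integers(2**31 - 1)),
        )
    zvals = np.array([r.zvalues["virtual_time"] for r in results.values()])
    group = group_signflip_test(zvals, n_flips=n_flips, seed=int(rng.integers(2**31 - 1)))
    return SubjectGroupAnalysis(results, "virtual_time", group,
                                meta={"n_perm": n_perm, "seed": seed})


class TimelineModel:
    """Model object for the timeline-construction analysis."""

    def __init__(self, behavior: pd.DataFrame, design: ExperimentDesign):
        self.behavior = behavior
        self.design = design

    def fit(self, n_perm: int = 10_000, seed: int | None = None,
            n_flips: int = 10_000) -> SubjectGroupAnalysis:
        return timeline_regression(self.behavior, self.design, n_perm=n_perm,
                                   seed=seed, n_flips=n_flips)


def accuracy_metrics(behavior: pd.DataFrame, design: ExperimentDesign) -> dict[str, pd.DataFrame]:
    """Mean absolute timeline errors per subject, position, sequence, speed."""
    m = signed_errors(behavior, design)
    m["abs_error"] = m["signed_error"].abs()
    speeds = design.clock_speeds
    m["clock_speed"] = m["sequence_id"].map(speeds)
    per_subject = m.groupby("subject_id")["abs_error"].mean().rename("mae").to_frame()
    by_position = m.groupby(["subject_id", "position"])["abs_error"].mean().unstack()
    by_sequence = m.groupby(["subject_id", "sequence_id"])["abs_error"].mean().unstack()
    by_speed = m.groupby(["subject_id", "clock_speed"])["abs_error"].mean().unstack()
    group = pd.DataFrame({
        "mean": [per_subject["mae"].mean()],
        "sd": [per_subject["mae"].std(ddof=1)],
    }, index=["mae"])
    return {"per_subject": per_subject, "by_position": by_position,
            "by_sequence": by_sequence, "by_clock_speed": by_speed, "group": group}


# ---------------------------------------------------------------------------
# sorting task
# ---------------------------------------------------------------------------

def assign_sorted_groups(
    sorted_groups: pd.Series | dict[int, int],
    design: ExperimentDesign,
) -> dict:
    """Score a sorting by the group-to-sequence mapping maximizing overlap.

    Returns percent correct, the optimal mapping, per-event correctness
    flags and the error events.  The optimum over the 4x4 overlap matrix is
    found with the Hungarian algorithm (equivalent to brute force over the
    24 mappings).
    """
    labels = pd.Series(sorted_groups)
    labels.index = labels.index.astype(int)
    ev = design.events.set_index("event_id")
    if set(labels.index) != set(ev.index):
        raise DesignValidationError("every event must be assigned to a group")
    group_ids = sorted(labels.unique())
    if len(group_ids) != N_SEQUENCES:
        raise DesignValidationError(
            f"expected {N_SEQUENCES} sorting groups, got {len(group_ids)}"
        )
    overlap = np.zeros((N_SEQUENCES, N_SEQUENCES), dtype=int)
    for event_id, g in labels.items():
        s = int(ev.loc[event_id, "sequence_id"])
        overlap[group_ids.index(g), s - 1] += 1
    rows, cols = linear_sum_assignment(-overlap)
    mapping = {group_ids[r]: int(c + 1) for r, c in zip(rows, cols)}
    assigned_seq = labels.map(mapping)
    correct = assigned_seq == ev.loc[labels.index, "sequence_id"]
    return {
        "percent_correct": 100.0 * correct.mean(),
        "mapping": mapping,
        "correct": correct,
        "n_errors": int((~correct).sum()),
        "assigned_sequence": assigned_seq,
    }


def _swap_error_events(assigned_seq: pd.Series, design: ExperimentDesign) -> set[int]:
    """Events involved in a mutual same-position interchange.

    Event A of sequence i placed where the same-position event B of
    sequence j belongs, and vice versa; one-sided misplacements count as
    plain errors.
    """
    ev = design.events.set_index("event_id")
    swaps: set[int] = set()
    mis = [e for e in assigned_seq.index
           if assigned_seq[e] != ev.loc[e, "sequence_id"]]
    for e in mis:
        pe, se, ge = ev.loc[e, "position"], ev.loc[e, "sequence_id"], assigned_seq[e]
        # the event occupying the same position in the sequence e was placed into
        partner = ev[(ev["position"] == pe) & (ev["sequence_id"] == ge)].index
        if len(partner) == 1 and partner[0] in mis:
            f = partner[0]
            if assigned_seq[f] == se:
                swaps.add(int(e))
                swaps.add(int(f))
    return swaps


def swap_error_test(
    behaviors: pd.DataFrame,
    design: ExperimentDesign,
    n_iter: int = 10_000,
    seed: int | None = None,
) -> dict:
    """Observed swap-error proportion vs a random-sorting-error surrogate.

    The observed proportion is the fraction of sorting errors (under the
    optimal assignment) that are mutual same-position swaps.  The surrogate
    introduces, per iteration, the per-subject matched number of errors by
    moving randomly chosen events to uniformly chosen wrong groups, and
    records the swap proportion of the surrogate sample.  p is the
    proportion of surrogate proportions at least as large as the observed
    one (add-one corrected); z standardizes the observed proportion by the
    null mean and sd.  A chi-square test of swap counts against uniformity
    over positions is attached.
    """
    ev = design.events.set_index("event_id")
    per_subject_errors: list[int] = []
    total_errors = 0
    total_swaps = 0
    swap_positions: list[int] = []
    for subject, grp in behaviors.groupby("subject_id"):
        labels = grp.set_index("event_id")["sorted_group"]
        res = assign_sorted_groups(labels, design)
        per_subject_errors.append(res["n_errors"])
        total_errors += res["n_errors"]
        swaps = _swap_error_events(res["assigned_sequence"], design)
        total_swaps += len(swaps)
        swap_positions.extend(int(ev.loc[e, "position"]) for e in swaps)
    if total_errors == 0:
        return {"undefined": True, "n_errors": 0, "observed_proportion": np.nan,
                "z": np.nan, "p": np.nan}
    observed = total_swaps / total_errors

    rng = np.random.default_rng(seed)
    event_ids = ev.index.to_numpy()
    seq = ev["sequence_id"].to_numpy()
    pos = ev["position"].to_numpy()
    # lookup: (sequence, position) -> row index
    slot = {(int(s), int(p)): k for k, (s, p) in enumerate(zip(seq, pos))}
    null = np.empty(n_iter)
    for it in range(n_iter):
        swaps_it = 0
        errs_it = 0
        for k_err in per_subject_errors:
            if k_err == 0:
                continue
            moved = rng.choice(len(event_ids), size=k_err, replace=False)
            wrong = np.empty(len(moved), dtype=int)
            for m, idx in enumerate(moved):
                choices = [s for s in range(1, N_SEQUENCES + 1) if s != seq[idx]]
                wrong[m] = choices[rng.integers(len(choices))]
            placed = dict(zip(moved.tolist(), wrong.tolist()))
            errs_it += len(moved)
            for idx, g in placed.items():
                partner = slot[(g, int(pos[idx]))]
                if placed.get(partner) == int(seq[idx]):
                    swaps_it += 1
        null[it] = swaps_it / errs_it
    p = (1.0 + np.sum(null >= observed)) / (1.0 + n_iter)
    sd = null.std()
    z = (observed - null.mean()) / sd if sd > 0 else np.nan
    counts = np.bincount(swap_positions, minlength=N_POSITIONS + 1)[1:]
    return {
        "undefined": False,
        "observed_proportion": float(observed),
        "n_errors": int(total_errors),
        "n_swap_errors": int(total_swaps),
        "null_mean": float(null.mean()),
        "null_sd": float(sd),
        "z": float(z),
        "p": float(p),
        "n_iter": n_iter,
        "position_counts": counts,
        "position_uniformity": chi_square_uniformity(counts),
    }


def chi_square_uniformity(error_counts: np.ndarray) -> dict:
    """Pearson chi-square of per-position counts against uniformity."""
    counts = np.asarray(error_counts, dtype=float)
    total = counts.sum()
    if total == 0:
        return {"undefined": True, "chi2": np.nan, "p": np.nan}
    chi2, p = stats.chisquare(counts)
    return {"undefined": False, "chi2": float(chi2), "p": float(p),
            "df": len(counts) - 1}


# ---------------------------------------------------------------------------
# generalization bias
# ---------------------------------------------------------------------------

def generalization_bias(
    behavior: pd.DataFrame,
    design: ExperimentDesign,
    n_perm: int = 10_000,
    seed: int | None = None,
    n_flips: int = 10_000,
) -> SubjectGroupAnalysis:
    """Signed construction errors regressed on the relative time of others.

    Per subject a linear regression of signed_error on the deviation of the
    other sequences' same-position mean time (20 points), permutation-Z via
    outcome shuffling, then a group sign-flip test.  Per-subject slopes are
    exposed for brain-behavior correlations.
    """
    pred = generalization_predictor(design)
    if pred["deviation"].std() == 0:
        raise DegeneratePredictorError(
            "deviation predictor is constant (identical times across sequences)"
        )
    m = signed_errors(behavior, design).merge(pred, on="event_id")
    X_template = pred.sort_values("event_id")[["deviation"]].reset_index(drop=True)
    rng = np.random.default_rng(seed)
    results: dict[int, SubjectModelResult] = {}
    for subject, grp in m.groupby("subject_id"):
        grp = grp.sort_values("event_id")
        y = grp["signed_error"].to_numpy(float)
        results[int(subject)] = permutation_z(
            y, X_template, focal=("deviation",), n_perm=n_perm,
            seed=int(rng.integers(2**31 - 1)),
        )
    zvals = np.array([r.zvalues["deviation"] for r in results.values()])
    group = group_signflip_test(zvals, n_flips=n_flips, seed=int(rng.integers(2**31 - 1)))
    return SubjectGroupAnalysis(results, "deviation", group,
                                meta={"n_perm": n_perm, "seed": seed})


class GeneralizationBiasModel:
    """Model object for the structural-knowledge generalization bias."""

    def __init__(self, behavior: pd.DataFrame, design: ExperimentDesign):
        self.behavior = behavior
        self.design = design

    def fit(self, n_perm: int = 10_000, seed: int | None = None,
            n_flips: int = 10_000) -> SubjectGroupAnalysis:
        return generalization_bias(self.behavior, self.design, n_perm=n_perm,
                                   seed=seed, n_flips=n_flips)


def brain_behavior_correlation(
    bias_slopes: np.ndarray, peak_tvalues: np.ndarray
) -> dict:
    """Spearman rank correlation between bias slopes and peak t-values."""
    x = np.asarray(bias_slopes, float)
    y = np.asarray(peak_tvalues, float)
    if len(x) != len(y):
        raise DesignValidationError("paired vectors must have equal length")
    if len(x) < 5:
        raise DesignValidationError("need at least 5 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        return {"undefined": True, "rho": np.nan, "p": np.nan}
    rho, p = stats.spearmanr(x, y)
    return {"undefined": False, "rho": float(rho), "p": float(p), "n": len(x)}
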