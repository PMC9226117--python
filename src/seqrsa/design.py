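"""Virtual-clock experiment design and pairwise time metrics.

The experiment consists of four event sequences ("virtual days") of five
events each.  Every event has a time on a hidden virtual clock (virtual
hours, constrained to the 6 a.m.-to-midnight interval [6, 24]), a sequence
position (order, 1-5), and a real time in seconds since the first event of
its sequence.  The virtual clock runs at a sequence-specific speed, which
partially dissociates virtual time from real time across sequences.

Every downstream analysis consumes the table of the 190 unordered event
pairs with their three distance metrics (virtual, order, real), a
same-sequence flag, and a first/last control flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import DesignValidationError, DegeneratePredictorError

N_SEQUENCES = 4
N_POSITIONS = 5
N_EVENTS = N_SEQUENCES * N_POSITIONS
N_PAIRS = N_EVENTS * (N_EVENTS - 1) // 2
VIRTUAL_DAY = (6.0, 24.0)  # timeline runs from 6 a.m. to midnight

DESIGN_COLUMNS = ["event_id", "sequence_id", "position", "virtual_time", "real_time"]
METRIC_COLUMNS = ["virtual_distance", "order_distance", "real_distance"]


@dataclass(frozen=True)
class ExperimentDesign:
    """The 20 events with their sequence membership and time metrics.

    Parameters
    ----------
    events
        DataFrame with columns ``event_id`` (1..20), ``sequence_id`` (1..4),
        ``position`` (1..5), ``virtual_time`` (virtual hours in [6, 24]) and
        ``real_time`` (seconds since the first event of the sequence).
    """

    events: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        ev = self.events
        missing = [c for c in DESIGN_COLUMNS if c not in ev.columns]
        if missing:
            raise DesignValidationError(f"design table missing columns {missing}")
        if len(ev) != N_EVENTS:
            raise DesignValidationError(
                f"expected {N_EVENTS} events, got {len(ev)} rows"
            )
        if sorted(ev["event_id"]) != list(range(1, N_EVENTS + 1)):
            raise DesignValidationError("event_id must enumerate 1..20 exactly once")
        dup = ev.duplicated(subset=["sequence_id", "position"])
        if dup.any():
            bad = ev.loc[dup, ["event_id", "sequence_id", "position"]].iloc[0]
            raise DesignValidationError(
                "duplicate (sequence_id, position): event_id="
                f"{bad.event_id} sequence={bad.sequence_id} position={bad.position}"
            )
        for seq, grp in ev.groupby("sequence_id"):
            grp = grp.sort_values("position")
            if sorted(grp["position"]) != list(range(1, N_POSITIONS + 1)):
                raise DesignValidationError(
                    f"sequence {seq} must hold positions 1..{N_POSITIONS}"
                )
            for col in ("virtual_time", "real_time"):
                if not np.all(np.diff(grp[col].to_numpy()) > 0):
                    raise DesignValidationError(
                        f"{col} not strictly increasing with position in sequence {seq}"
                    )
        vt = ev["virtual_time"].to_numpy(float)
        if vt.min() < VIRTUAL_DAY[0] or vt.max() > VIRTUAL_DAY[1]:
            raise DesignValidationError(
                f"virtual_time must lie within {VIRTUAL_DAY}"
            )

    # -- derived quantities -------------------------------------------------

    @property
    def clock_speeds(self) -> dict[int, float]:
        """Virtual hours per real second, per sequence (from total spans)."""
        out: dict[int, float] = {}
        for seq, grp in self.events.groupby("sequence_id"):
            grp = grp.sort_values("position")
            dv = grp["virtual_time"].iloc[-1] - grp["virtual_time"].iloc[0]
            dr = grp["real_time"].iloc[-1] - grp["real_time"].iloc[0]
            out[int(seq)] = float(dv / dr)
        return out

    def metric_correlations(self) -> dict[str, float]:
        """Pearson correlations of virtual time with order and real time.

        Computed across the 20 events; the clock-speed manipulation keeps
        these high but below 1, partially dissociating the three metrics.
        """
        ev = self.events
        vt = ev["virtual_time"].to_numpy(float)
        return {
            "virtual_order": float(np.corrcoef(vt, ev["position"])[0, 1]),
            "virtual_real": float(np.corrcoef(vt, ev["real_time"])[0, 1]),
        }

    # -- IO -----------------------------------------------------------------

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ExperimentDesign":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path: str | Path) -> None:
        self.events.to_csv(path, sep="\t", index=False)


def build_pair_table(design: ExperimentDesign) -> pd.DataFrame:
    """All 190 unordered event pairs with distances and flags.

    Columns: ``event_i``, ``event_j`` (i < j), the three absolute distance
    metrics, ``same_sequence`` and ``first_last`` (a same-sequence pair of a
    position-1 and a position-5 event).  Cross-sequence real distances use
    each event's within-sequence real-time clock, mirroring how the
    predictors enter the regressions.
    """
    ev = design.events.set_index("event_id").sort_index()
    rows = []
    for i, j in combinations(range(1, N_EVENTS + 1), 2):
        a, b = ev.loc[i], ev.loc[j]
        same = a["sequence_id"] == b["sequence_id"]
        first_last = bool(
            same and {int(a["position"]), int(b["position"])} == {1, N_POSITIONS}
        )
        rows.append(
            {
                "event_i": i,
                "event_j": j,
                "virtual_distance": abs(a["virtual_time"] - b["virtual_time"]),
                "order_distance": abs(int(a["position"]) - int(b["position"])),
                "real_distance": abs(a["real_time"] - b["real_time"]),
                "same_sequence": bool(same),
                "first_last": first_last,
            }
        )
    return pd.DataFrame(rows)


def select_pairs(pairs: pd.DataFrame, subset: str) -> pd.DataFrame:
    """Select pair rows: ``'same'``, ``'different'`` or ``'all'``."""
    if subset == "same":
        return pairs[pairs["same_sequence"]]
    if subset == "different":
        return pairs[~pairs["same_sequence"]]
    if subset == "all":
        return pairs
    raise ValueError(f"unknown pair subset {subset!r}")


def zscore(x: np.ndarray | pd.Series, ddof: int = 1) -> np.ndarray:
    """Standardize to mean 0, sd 1 (sample sd); errors on zero variance."""
    arr = np.asarray(x, dtype=float)
    sd = arr.std(ddof=ddof)
    if sd == 0 or not np.isfinite(sd):
        raise DegeneratePredictorError("zero-variance column cannot be z-scored")
    return (arr - arr.mean()) / sd


def zscore_predictors(
    pairs: pd.DataFrame,
    subset: str = "all",
    columns: tuple[str, ...] | list[str] = tuple(METRIC_COLUMNS),
) -> pd.DataFrame:
    """Z-score metric columns within the pair subset entering a model.

    Standardization is recomputed within the subset actually analyzed
    (same-sequence rows, different-sequence rows, or all rows), so a metric
    enters every model with mean 0 and unit sd over the rows it is fit on.
    """
    sel = select_pairs(pairs, subset)
    if len(sel) < 3:
        raise DesignValidationError("pair subset must have at least 3 rows")
    out = sel.copy()
    for col in columns:
        out[col] = zscore(sel[col])
    return out


def write_pair_table(pairs: pd.DataFrame, path: str | Path) -> None:
    pairs.to_csv(path, sep="\t", index=False)
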