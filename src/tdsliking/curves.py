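"""Time-normalized TDS and TL curves built from raw trial records.

Each trial is resampled as a piecewise-constant (last-event-carried-forward)
step function on a common normalized time grid t' = t / duration in [0, 1].
Per panelist and condition, the three TDS repetitions aggregate into
dominance proportions (fraction of trials in which each attribute is the
current selection) and the three TL repetitions average into a mean liking
curve. The period before the first button press contributes "none" mass
(TDS) or a liking of 0 (TL).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .design import ATTRIBUTES
from .panel import TrialRecord

NONE_CHANNEL = "none"
TL_CHANNEL = "TL"

Provenance = Literal["panelist", "panel-mean", "bootstrap-replicate"]


@dataclass(frozen=True)
class TimeGrid:
    """Evenly spaced normalized-time grid on [0, 1] inclusive."""

    n_points: int = 101

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("grid needs at least 2 points")

    @property
    def points(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, self.n_points)


@dataclass(frozen=True, eq=False)
class TDSCurve:
    """Dominance proportions, one row per attribute, on a TimeGrid.

    ``none`` holds the residual mass (trials with no selection yet) so that
    attribute mass + none mass = 1 at every grid point. Only the 12
    attribute rows feed the prediction model.
    """

    grid: TimeGrid
    proportions: np.ndarray  # [n_attributes x n_points]
    none: np.ndarray  # [n_points]
    n_trials: int

    def __post_init__(self) -> None:
        p = self.proportions
        if p.shape != (len(ATTRIBUTES), self.grid.n_points):
            raise ValueError(f"proportions must be [{len(ATTRIBUTES)} x {self.grid.n_points}]")
        if (p < -1e-12).any() or (p > 1 + 1e-12).any():
            raise ValueError("proportions must lie in [0, 1]")


@dataclass(frozen=True, eq=False)
class TLCurve:
    """Mean liking over normalized time; 0 marks the pre-first-press period."""

    grid: TimeGrid
    liking: np.ndarray  # [n_points]

    def __post_init__(self) -> None:
        if self.liking.shape != (self.grid.n_points,):
            raise ValueError("liking vector length must match the grid")
        if (self.liking < -1e-12).any() or (self.liking > 9 + 1e-12).any():
            raise ValueError("liking values must lie in [0, 9]")


@dataclass(frozen=True, eq=False)
class CurveSet:
    """A paired (TDS, TL) curve set for one condition."""

    condition_id: str
    tds: TDSCurve
    tl: TLCurve
    provenance: Provenance
    replicate_id: str = ""

    def __post_init__(self) -> None:
        if self.tds.grid != self.tl.grid:
            raise ValueError("TDS and TL curves must share one grid")

    @property
    def grid(self) -> TimeGrid:
        return self.tds.grid


def trial_to_step_function(trial: TrialRecord, grid: TimeGrid) -> np.ndarray:
    """Sample a trial as a step function on the normalized grid.

    Returns an object array (TDS: attribute names / None) or a float array
    (TL: liking values, 0 before the first press). The value at grid point
    t is the payload of the last event with normalized time <= t.
    """
    times = np.array([t / trial.duration_s for t, _ in trial.events])
    pts = grid.points
    # index of last event at or before each grid point; -1 = before first event
    idx = np.searchsorted(times, pts, side="right") - 1
    if trial.task == "TL":
        payloads = np.array([float(v) for _, v in trial.events], dtype=float)
        out = np.zeros(grid.n_points)
        mask = idx >= 0
        out[mask] = payloads[idx[mask]]
        return out
    payloads_o = np.array([v for _, v in trial.events], dtype=object)
    out_o = np.full(grid.n_points, None, dtype=object)
    mask = idx >= 0
    out_o[mask] = payloads_o[idx[mask]]
    return out_o


def build_panelist_curves(trials: Sequence[TrialRecord], grid: TimeGrid) -> CurveSet:
    """Aggregate one panelist's repetitions on one condition into a curve pair.

    TDS proportions are the fraction of that panelist's TDS repetitions in
    which each attribute is dominant at each grid point; TL is the mean of
    the TL repetitions' step functions.
    """
    if not trials:
        raise ValueError("no trials given")
    pids = {t.panelist_id for t in trials}
    cids = {t.condition_id for t in trials}
    if len(pids) != 1 or len(cids) != 1:
        raise ValueError("trials must share one panelist and one condition")
    tds_trials = [t for t in trials if t.task == "TDS"]
    tl_trials = [t for t in trials if t.task == "TL"]
    if not tds_trials or not tl_trials:
        raise ValueError("need at least one TDS and one TL trial")

    counts = np.zeros((len(ATTRIBUTES), grid.n_points))
    none = np.zeros(grid.n_points)
    for tr in tds_trials:
        step = trial_to_step_function(tr, grid)
        for j, val in enumerate(step):
            if val is None:
                none[j] += 1
            else:
                counts[ATTRIBUTES.index(val), j] += 1
    n = len(tds_trials)
    tds = TDSCurve(grid, counts / n, none / n, n_trials=n)

    liking = np.mean([trial_to_step_function(tr, grid) for tr in tl_trials], axis=0)
    tl = TLCurve(grid, liking)
    return CurveSet(cids.pop(), tds, tl, provenance="panelist", replicate_id=pids.pop())


def build_panel_mean(curve_sets: Sequence[CurveSet]) -> CurveSet:
    """Unweighted pointwise mean of panelist curve sets (one condition)."""
    if not curve_sets:
        raise ValueError("no curve sets given")
    cids = {cs.condition_id for cs in curve_sets}
    grids = {cs.grid for cs in curve_sets}
    if len(cids) != 1 or len(grids) != 1:
        raise ValueError("curve sets must share one condition and one grid")
    grid = grids.pop()
    props = np.mean([cs.tds.proportions for cs in curve_sets], axis=0)
    none = np.mean([cs.tds.none for cs in curve_sets], axis=0)
    liking = np.mean([cs.tl.liking for cs in curve_sets], axis=0)
    n = sum(cs.tds.n_trials for cs in curve_sets)
    return CurveSet(
        cids.pop(),
        TDSCurve(grid, props, none, n_trials=n),
        TLCurve(grid, liking),
        provenance="panel-mean",
        replicate_id="mean",
    )


def build_condition_curves(
    trials: Iterable[TrialRecord], grid: TimeGrid | None = None
) -> dict[str, list[CurveSet]]:
    """Per-panelist curve sets for every condition present in a trial log."""
    grid = grid or TimeGrid()
    by_key: dict[tuple[str, str], list[TrialRecord]] = {}
    for tr in trials:
        by_key.setdefault((tr.condition_id, tr.panelist_id), []).append(tr)
    out: dict[str, list[CurveSet]] = {}
    for (cid, _pid), group in sorted(by_key.items()):
        out.setdefault(cid, []).append(build_panelist_curves(group, grid))
    return out


# ---------------------------------------------------------------------------
# long-format curve CSV round trip


def curves_to_frame(curve_sets: Iterable[CurveSet]) -> pd.DataFrame:
    rows = []
    for cs in curve_sets:
        pts = cs.grid.points
        for i, attr in enumerate(ATTRIBUTES):
            for j, t in enumerate(pts):
                rows.append((cs.condition_id, cs.provenance, cs.replicate_id, attr, t, cs.tds.proportions[i, j]))
        for j, t in enumerate(pts):
            rows.append((cs.condition_id, cs.provenance, cs.replicate_id, NONE_CHANNEL, t, cs.tds.none[j]))
        for j, t in enumerate(pts):
            rows.append((cs.condition_id, cs.provenance, cs.replicate_id, TL_CHANNEL, t, cs.tl.liking[j]))
    return pd.DataFrame(
        rows, columns=["condition_id", "provenance", "replicate_id", "channel", "t", "value"]
    )


def write_curves(path, curve_sets: Iterable[CurveSet]) -> None:
    curves_to_frame(curve_sets).to_csv(path, index=False, encoding="utf-8")


def read_curves(path) -> list[CurveSet]:
    df = pd.read_csv(
        path, dtype={"replicate_id": str}, keep_default_na=False,
        float_precision="round_trip",
    )
    out: list[CurveSet] = []
    for (cid, prov, rid), grp in df.groupby(
        ["condition_id", "provenance", "replicate_id"], sort=False
    ):
        n_points = grp["t"].nunique()
        grid = TimeGrid(n_points)
        wide = grp.pivot_table(index="channel", columns="t", values="value", sort=True)
        props = wide.loc[list(ATTRIBUTES)].to_numpy()
        none = wide.loc[NONE_CHANNEL].to_numpy()
        liking = wide.loc[TL_CHANNEL].to_numpy()
        out.append(
            CurveSet(
                str(cid),
                TDSCurve(grid, props, none, n_trials=0),
                TLCurve(grid, liking),
                provenance=str(prov),  # type: ignore[arg-type]
                replicate_id=str(rid),
            )
        )
    return out


def group_by_condition(curve_sets: Iterable[CurveSet]) -> dict[str, list[CurveSet]]:
    out: dict[str, list[CurveSet]] = {}
    for cs in curve_sets:
        out.setdefault(cs.condition_id, []).append(cs)
    return out
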