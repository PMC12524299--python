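"""Bootstrap data augmentation over panelist curve pairs.

Each replicate draws ``n_sampled`` panelists with replacement (TDS and TL
curves drawn together, preserving the within-panelist coupling the model
must learn) and averages them into one curve pair; repeating this yields
``n_replicates`` augmented curve sets per condition. This is augmentation,
not uncertainty quantification.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .curves import CurveSet, TDSCurve, TLCurve, build_panel_mean


@dataclass(frozen=True)
class ResampleConfig:
    n_replicates: int = 100
    n_sampled: int | None = None  # default: panel size
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.n_sampled is not None and self.n_sampled < 1:
            raise ValueError("n_sampled must be >= 1")


def bootstrap_condition(
    panelist_sets: Sequence[CurveSet], cfg: ResampleConfig
) -> list[CurveSet]:
    """Resample one condition's panelist curve pairs into replicates.

    Deterministic in ``cfg.seed``. Replicates are the unweighted mean of the
    drawn panelists' curves and carry provenance ``bootstrap-replicate``.
    """
    if not panelist_sets:
        raise ValueError("no panelist curve sets given")
    cids = {cs.condition_id for cs in panelist_sets}
    grids = {cs.grid for cs in panelist_sets}
    if len(cids) != 1 or len(grids) != 1:
        raise ValueError("panelist sets must share one condition and one grid")
    cid = cids.pop()
    grid = grids.pop()
    n_sampled = cfg.n_sampled or len(panelist_sets)

    props = np.stack([cs.tds.proportions for cs in panelist_sets])
    nones = np.stack([cs.tds.none for cs in panelist_sets])
    liking = np.stack([cs.tl.liking for cs in panelist_sets])
    n_trials = np.array([cs.tds.n_trials for cs in panelist_sets])

    rng = np.random.default_rng(cfg.seed)
    out: list[CurveSet] = []
    for b in range(cfg.n_replicates):
        idx = rng.integers(0, len(panelist_sets), size=n_sampled)
        out.append(
            CurveSet(
                cid,
                TDSCurve(grid, props[idx].mean(axis=0), nones[idx].mean(axis=0),
                         n_trials=int(n_trials[idx].sum())),
                TLCurve(grid, liking[idx].mean(axis=0)),
                provenance="bootstrap-replicate",
                replicate_id=f"b{b + 1:04d}",
            )
        )
    return out


def bootstrap_dataset(
    per_condition: Mapping[str, Sequence[CurveSet]],
    n_replicates: int = 100,
    seed: int = 0,
) -> dict[str, list[CurveSet]]:
    """Independent bootstrap draws for every condition.

    Per-condition seeds are spawned from ``seed`` keyed by the position of
    the condition in sorted order, so conditions are independent and the
    whole dataset is reproducible.
    """
    ss = np.random.SeedSequence(seed)
    out: dict[str, list[CurveSet]] = {}
    for sub, cid in zip(ss.spawn(len(per_condition)), sorted(per_condition)):
        sub_seed = int(sub.generate_state(1)[0] % (2**31))
        cfg = ResampleConfig(n_replicates=n_replicates, seed=sub_seed)
        out[cid] = bootstrap_condition(per_condition[cid], cfg)
    return out
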