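"""End-to-end synthetic datasets for the prediction pipeline.

``default_dataset`` runs the whole front half of the pipeline at the study
scale: 16 panelists x 8 conditions x 3 repetitions per task, per-panelist
curves on a 101-point normalized grid, and 100 bootstrap replicates per
condition.

``linear_liking_dataset`` is the controlled recovery benchmark: it keeps
realistic TDS dynamics but replaces the liking curve of every replicate by
a known fixed linear functional of the current dominance-proportion vector
plus Gaussian noise, so that a working model must beat the best constant
predictor by a wide margin.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .bootstrap import bootstrap_dataset
from .curves import CurveSet, TDSCurve, TimeGrid, TLCurve, build_condition_curves
from .design import (
    ATTRIBUTES,
    ConditionProfile,
    FoodCondition,
    StudyDesign,
    default_profiles,
)
from .panel import generate_session

Dataset = dict[str, list[CurveSet]]


def condition_map(design: StudyDesign) -> dict[str, FoodCondition]:
    return {c.condition_id: c for c in design.conditions}


def default_dataset(
    seed: int = 0,
    design: StudyDesign | None = None,
    profiles: Mapping[str, ConditionProfile] | None = None,
    n_replicates: int = 100,
    n_points: int = 101,
) -> tuple[Dataset, dict[str, FoodCondition], Dataset]:
    """Simulate, build curves, and bootstrap at the default study scale.

    Returns ``(replicates, conditions, panelist_sets)`` where ``replicates``
    maps condition -> ``n_replicates`` bootstrap curve sets and
    ``panelist_sets`` maps condition -> per-panelist curve sets.
    """
    design = design or StudyDesign()
    profiles = profiles or default_profiles()
    ss = np.random.SeedSequence(seed)
    sim_seed, boot_seed = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))
    trials = generate_session(design, profiles, sim_seed)
    panelist_sets = build_condition_curves(trials, TimeGrid(n_points))
    replicates = bootstrap_dataset(panelist_sets, n_replicates=n_replicates, seed=boot_seed)
    return replicates, condition_map(design), panelist_sets


def linear_liking_weights() -> tuple[np.ndarray, float]:
    """The fixed (weights, intercept) of the linear recovery benchmark.

    Weights span roughly 3.5-7 liking points across attributes with a unit
    intercept, so true liking stays inside [0, 9] for any dominance vector.
    """
    weights = np.array([5.5, 4.0, 5.5, 3.5, 5.5, 4.5, 5.0, 5.5, 4.5, 6.5, 5.5, 4.5])
    return weights, 1.0


def linear_liking_dataset(
    seed: int = 0,
    noise_sd: float = 0.3,
    n_replicates: int = 100,
    design: StudyDesign | None = None,
    n_points: int = 101,
) -> tuple[Dataset, dict[str, FoodCondition]]:
    """Bootstrap replicates whose TL curve is a known linear readout of TDS.

    For every replicate, liking(t) = b + w . p(t) + N(0, noise_sd), where
    p(t) is the 12-dimensional dominance-proportion vector, clipped to the
    [0, 9] display range (the clip almost never binds at the default noise).
    """
    replicates, conditions, _ = default_dataset(
        seed=seed, design=design, n_replicates=n_replicates, n_points=n_points
    )
    weights, intercept = linear_liking_weights()
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(99,)))
    out: Dataset = {}
    for cid in sorted(replicates):
        sets = []
        for cs in replicates[cid]:
            y = intercept + weights @ cs.tds.proportions
            y = y + rng.normal(0.0, noise_sd, size=y.shape)
            sets.append(
                CurveSet(
                    cid,
                    cs.tds,
                    TLCurve(cs.grid, np.clip(y, 0.0, 9.0)),
                    provenance="bootstrap-replicate",
                    replicate_id=cs.replicate_id,
                )
            )
        out[cid] = sets
    return out, conditions
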