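"""Leave-one-pairing-out evaluation and architecture ranking.

For each of the four cracker-spread pairings, a fresh reservoir is trained
on every bootstrap replicate of the other seven conditions (7 x B curve
sets; 700 at the default B=100) and asked to predict the TL curve of each
held-out replicate from its TDS curves and auxiliary flags. The per-curve-set
RMSE distribution is summarized by its median and interquartile range
(linear-interpolation, "type 7", quantiles), per pairing and pooled over
all pairings; architectures are ranked by the pooled median.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .curves import CurveSet, TLCurve
from .design import FoodCondition
from .encoding import EncodingConfig, aux_dimension
from .esn import ESNParams, TemporalLikingESN

NEURON_GRID = (64, 128, 192, 256)
ENCODING_GRID = (
    "none",
    "combo",
    "cracker_spread",
    "exclusive3",
    "brand",
    "brand_combo",
    "brand_cs",
    "brand_all",
)


def pairing_ids(conditions: Mapping[str, FoodCondition]) -> list[str]:
    return sorted(cid for cid, c in conditions.items() if c.is_pairing)


def loco_split(
    dataset: Mapping[str, Sequence[CurveSet]],
    held_out: str,
    conditions: Mapping[str, FoodCondition],
) -> tuple[list[CurveSet], list[CurveSet]]:
    """Split replicates into (train on 7 conditions, test on the held-out pairing)."""
    if held_out not in dataset:
        raise ValueError(f"condition {held_out!r} not in dataset")
    if not conditions[held_out].is_pairing:
        raise ValueError(f"held-out condition must be a pairing, got {held_out!r}")
    train = [cs for cid in sorted(dataset) if cid != held_out for cs in dataset[cid]]
    test = list(dataset[held_out])
    return train, test


def rmse(predicted: TLCurve | np.ndarray, observed: TLCurve | np.ndarray) -> float:
    """Root mean squared error between two curves on the same grid."""
    p = predicted.liking if isinstance(predicted, TLCurve) else np.asarray(predicted, float)
    o = observed.liking if isinstance(observed, TLCurve) else np.asarray(observed, float)
    if p.shape != o.shape:
        raise ValueError(f"grid mismatch: {p.shape} vs {o.shape}")
    return float(np.sqrt(np.mean((p - o) ** 2)))


def median_iqr(values: np.ndarray) -> tuple[float, float, float]:
    """(median, q1, q3) with linear-interpolation quantiles."""
    v = np.asarray(values, float)
    return float(np.median(v)), float(np.percentile(v, 25)), float(np.percentile(v, 75))


@dataclass(frozen=True)
class EvalResult:
    """RMSE distributions of one architecture under LOCO evaluation."""

    n_neurons: int
    aux_config: str
    per_pairing: Mapping[str, np.ndarray]  # pairing -> B RMSE values
    pooling: str = "pooled"

    @property
    def architecture(self) -> str:
        return f"{self.n_neurons}/{self.aux_config}"

    @property
    def n_flags(self) -> int:
        if self.aux_config not in ENCODING_GRID:
            return 0  # e.g. the constant-baseline pseudo-architecture
        return aux_dimension(EncodingConfig(self.aux_config))

    def pairing_stats(self, pairing: str) -> tuple[float, float, float]:
        return median_iqr(self.per_pairing[pairing])

    @property
    def pooled_values(self) -> np.ndarray:
        return np.concatenate([self.per_pairing[p] for p in sorted(self.per_pairing)])

    @property
    def pooled_stats(self) -> tuple[float, float, float]:
        if self.pooling == "median-of-medians":
            meds = np.array([np.median(v) for v in self.per_pairing.values()])
            return float(np.median(meds)), float(np.percentile(meds, 25)), float(np.percentile(meds, 75))
        return median_iqr(self.pooled_values)

    @property
    def pooled_median(self) -> float:
        return self.pooled_stats[0]

    def to_dict(self) -> dict:
        return {
            "n_neurons": self.n_neurons,
            "aux_config": self.aux_config,
            "n_flags": self.n_flags,
            "pooling": self.pooling,
            "pooled": dict(zip(("median", "q1", "q3"), self.pooled_stats)),
            "per_pairing": {
                p: {
                    **dict(zip(("median", "q1", "q3"), self.pairing_stats(p))),
                    "rmse": np.asarray(v, float).tolist(),
                }
                for p, v in self.per_pairing.items()
            },
        }


def evaluate_architecture(
    n_neurons: int,
    aux_config: str,
    dataset: Mapping[str, Sequence[CurveSet]],
    conditions: Mapping[str, FoodCondition],
    esn_params: ESNParams | None = None,
    seed: int = 0,
    clip: bool = False,
    pooling: str = "pooled",
) -> EvalResult:
    """LOCO-evaluate one (neuron count, encoding) architecture.

    One freshly initialized reservoir per held-out pairing (sub-seeded from
    ``seed``), trained on the pooled states of the seven training
    conditions' replicates. Deterministic in ``seed``.
    """
    params = replace(esn_params or ESNParams(), n_neurons=n_neurons)
    per_pairing: dict[str, np.ndarray] = {}
    for k, pairing in enumerate(pairing_ids(conditions)):
        train, test = loco_split(dataset, pairing, conditions)
        sub_seed = int(
            np.random.SeedSequence(seed, spawn_key=(k,)).generate_state(1)[0] % (2**31)
        )
        model = TemporalLikingESN(
            train, conditions, encoding=aux_config, params=replace(params, seed=sub_seed)
        )
        res = model.fit()
        preds = res.predict_many(test, clip=clip)
        per_pairing[pairing] = np.array(
            [rmse(p, cs.tl.liking) for p, cs in zip(preds, test)]
        )
    return EvalResult(n_neurons, aux_config, per_pairing, pooling=pooling)


def constant_baseline_result(
    dataset: Mapping[str, Sequence[CurveSet]],
    conditions: Mapping[str, FoodCondition],
    pooling: str = "pooled",
) -> EvalResult:
    """LOCO RMSEs of the best-constant predictor (training grand-mean liking).

    The reference point for parameter-recovery checks: a model that ignores
    the TDS input entirely and always answers the training pool's mean
    liking value.
    """
    per_pairing: dict[str, np.ndarray] = {}
    for pairing in pairing_ids(conditions):
        train, test = loco_split(dataset, pairing, conditions)
        grand_mean = float(np.mean([cs.tl.liking for cs in train]))
        per_pairing[pairing] = np.array(
            [rmse(np.full_like(cs.tl.liking, grand_mean), cs.tl.liking) for cs in test]
        )
    return EvalResult(0, "constant-baseline", per_pairing, pooling=pooling)


def sweep_architectures(
    dataset: Mapping[str, Sequence[CurveSet]],
    conditions: Mapping[str, FoodCondition],
    neurons: Sequence[int] = NEURON_GRID,
    encodings: Sequence[str] = ENCODING_GRID,
    esn_params: ESNParams | None = None,
    seed: int = 0,
    clip: bool = False,
    pooling: str = "pooled",
) -> list[EvalResult]:
    """Evaluate every (neuron count x encoding) architecture combination."""
    results = []
    for i, n in enumerate(neurons):
        for j, enc in enumerate(encodings):
            arch_seed = int(
                np.random.SeedSequence(seed, spawn_key=(i, j)).generate_state(1)[0] % (2**31)
            )
            results.append(
                evaluate_architecture(
                    n, enc, dataset, conditions, esn_params, seed=arch_seed,
                    clip=clip, pooling=pooling,
                )
            )
    return results


def rank_architectures(results: Sequence[EvalResult]) -> pd.DataFrame:
    """Ranked report: ascending pooled median, ties by IQR width then name.

    One row per architecture with pooled and per-pairing "median (q1-q3)"
    columns, mirroring the usual model-comparison table for this design.
    """
    if not results:
        raise ValueError("no results to rank")

    def sort_key(r: EvalResult):
        m, q1, q3 = r.pooled_stats
        return (m, q3 - q1, r.architecture)

    ordered = sorted(results, key=sort_key)
    pairings = sorted(ordered[0].per_pairing)
    rows = []
    for rank, r in enumerate(ordered, start=1):
        m, q1, q3 = r.pooled_stats
        row = {
            "rank": rank,
            "neurons": r.n_neurons,
            "flags": r.n_flags,
            "aux_config": r.aux_config,
            "all_pairs": f"{m:.2f} ({q1:.2f}-{q3:.2f})",
            "pooled_median": m,
        }
        for p in pairings:
            pm, pq1, pq3 = r.pairing_stats(p)
            row[p] = f"{pm:.2f} ({pq1:.2f}-{pq3:.2f})"
        rows.append(row)
    return pd.DataFrame(rows)


def write_results_json(path, results: Sequence[EvalResult]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump([r.to_dict() for r in results], fh, indent=1)


def read_results_json(path) -> list[EvalResult]:
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    return [
        EvalResult(
            d["n_neurons"],
            d["aux_config"],
            {p: np.array(v["rmse"]) for p, v in d["per_pairing"].items()},
            pooling=d.get("pooling", "pooled"),
        )
        for d in raw
    ]
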