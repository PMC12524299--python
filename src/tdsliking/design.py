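"""Study design constants and generative condition profiles.

The panel design mirrors a crackers-and-spreads tasting study: two crackers
(plain, sesame), two spreads (peanut, strawberry) and their four binary
pairings — eight tasting conditions — evaluated by a 16-member panel with
two real-time tasks (temporal dominance of sensations, TDS, and temporal
liking, TL), each repeated three times per condition.

A :class:`ConditionProfile` is the generative description of one condition
used by the synthetic panel: an ordered set of phases on normalized time,
each with an attribute-selection probability vector, plus hedonic weights
mapping the currently dominant attribute to a liking level on the 1-9 scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import yaml

#: The twelve sensory attributes, in vocabulary order.
ATTRIBUTES: tuple[str, ...] = (
    "aromatic",
    "burned",
    "buttery",
    "dry",
    "nutty",
    "salty",
    "sesame-like",
    "smooth",
    "sour",
    "sweet",
    "wet",
    "wheat-like",
)

CRACKERS = ("plain", "sesame")
SPREADS = ("peanut", "strawberry")

LIKING_MIN, LIKING_MAX = 1, 9


class ConfigurationError(ValueError):
    """Raised when a design, profile or encoding configuration is invalid."""


@dataclass(frozen=True)
class FoodCondition:
    """One tasting condition: a cracker, a spread, or a cracker-spread pairing."""

    condition_id: str
    cracker: str | None = None
    spread: str | None = None

    def __post_init__(self) -> None:
        if self.cracker is None and self.spread is None:
            raise ConfigurationError(
                f"condition {self.condition_id!r} has neither cracker nor spread"
            )
        if self.cracker is not None and self.cracker not in CRACKERS:
            raise ConfigurationError(f"unknown cracker {self.cracker!r}")
        if self.spread is not None and self.spread not in SPREADS:
            raise ConfigurationError(f"unknown spread {self.spread!r}")

    @property
    def is_pairing(self) -> bool:
        return self.cracker is not None and self.spread is not None

    @property
    def duration_class(self) -> str:
        """'spread' (short tastings, ~10 s) or 'cracker' (~20 s, incl. pairings)."""
        return "spread" if self.cracker is None else "cracker"


def default_conditions() -> tuple[FoodCondition, ...]:
    """The eight conditions: 2 crackers + 2 spreads + 4 pairings."""
    singles = [FoodCondition(c, cracker=c) for c in CRACKERS]
    singles += [FoodCondition(s, spread=s) for s in SPREADS]
    pairs = [
        FoodCondition(f"{c}-{s}", cracker=c, spread=s)
        for c in CRACKERS
        for s in SPREADS
    ]
    return tuple(singles + pairs)


@dataclass(frozen=True)
class StudyDesign:
    """Panel dimensions and per-condition-class tasting durations."""

    n_panelists: int = 16
    n_repetitions: int = 3
    conditions: tuple[FoodCondition, ...] = field(default_factory=default_conditions)
    attributes: tuple[str, ...] = ATTRIBUTES
    mean_duration_s: Mapping[str, float] = field(
        default_factory=lambda: {"cracker": 20.0, "spread": 10.0}
    )
    duration_cv: float = 0.15  # lognormal coefficient of variation

    def __post_init__(self) -> None:
        if self.n_panelists < 0:
            raise ConfigurationError("n_panelists must be nonnegative")
        if len(set(self.attributes)) != len(self.attributes):
            raise ConfigurationError("attributes must be unique")
        ids = [c.condition_id for c in self.conditions]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("condition ids must be unique")

    @property
    def trials_per_panelist(self) -> int:
        return len(self.conditions) * 2 * self.n_repetitions

    def condition(self, condition_id: str) -> FoodCondition:
        for c in self.conditions:
            if c.condition_id == condition_id:
                return c
        raise ConfigurationError(f"unknown condition {condition_id!r}")

    def duration_mean(self, condition: FoodCondition) -> float:
        return float(self.mean_duration_s[condition.duration_class])


@dataclass(frozen=True)
class ConditionProfile:
    """Generative profile for one condition.

    phases
        Ordered ``((t0, t1), p)`` pairs tiling [0, 1]; ``p`` is a selection
        probability vector over the 12 attributes used for episodes starting
        in that phase.
    hedonic_weights
        Per-attribute liking contribution on the 1-9 scale; the TL generator
        reads the weight of the currently dominant attribute.
    dwell_mean_s
        Mean dwell time of a dominant-attribute episode (exponential).
    press_rate
        TL press events per unit of normalized time.
    noise_sd
        SD of the Gaussian noise added to liking before rounding/clipping.
    baseline_liking
        Liking level reported while no attribute is dominant yet.
    """

    phases: tuple[tuple[tuple[float, float], np.ndarray], ...]
    hedonic_weights: np.ndarray
    dwell_mean_s: float = 2.5
    press_rate: float = 12.0
    noise_sd: float = 0.8
    baseline_liking: float = 5.0
    tds_delay_frac: float = 0.05  # mean first-selection delay, fraction of duration
    tl_delay_frac: float = 0.10  # mean first-press delay, fraction of duration

    def __post_init__(self) -> None:
        edges = [iv for iv, _ in self.phases]
        if not edges or abs(edges[0][0]) > 1e-12 or abs(edges[-1][1] - 1.0) > 1e-12:
            raise ConfigurationError("phases must tile [0, 1]")
        for (a, b), nxt in zip(edges, edges[1:]):
            if abs(b - nxt[0]) > 1e-12:
                raise ConfigurationError("phase intervals must tile [0,1] contiguously")
        for _, p in self.phases:
            p = np.asarray(p, dtype=float)
            if p.shape != (len(ATTRIBUTES),) or (p < 0).any() or abs(p.sum() - 1) > 1e-9:
                raise ConfigurationError(
                    "each phase probability vector must be a length-12 distribution"
                )
        if np.asarray(self.hedonic_weights, float).shape != (len(ATTRIBUTES),):
            raise ConfigurationError("hedonic_weights must have one entry per attribute")

    def phase_probs(self, t: float) -> np.ndarray:
        """Selection probability vector active at normalized time ``t``."""
        t = min(max(t, 0.0), 1.0)
        for (a, b), p in self.phases:
            if a <= t < b:
                return p
        return self.phases[-1][1]


def _probs(d: Mapping[str, float]) -> np.ndarray:
    """Dense probability vector over ATTRIBUTES from a sparse dict, normalized."""
    v = np.zeros(len(ATTRIBUTES))
    for name, w in d.items():
        v[ATTRIBUTES.index(name)] = w
    s = v.sum()
    if s <= 0:
        raise ConfigurationError("phase weights must have positive mass")
    return v / s


def _weights(overrides: Mapping[str, float] | None = None) -> np.ndarray:
    base = {
        "aromatic": 6.0,
        "burned": 4.5,
        "buttery": 6.0,
        "dry": 4.0,
        "nutty": 6.0,
        "salty": 5.0,
        "sesame-like": 5.5,
        "smooth": 6.0,
        "sour": 5.0,
        "sweet": 7.0,
        "wet": 6.0,
        "wheat-like": 5.0,
    }
    if overrides:
        base.update(overrides)
    return np.array([base[a] for a in ATTRIBUTES])


def default_profiles() -> dict[str, ConditionProfile]:
    """Hand-set generative profiles for the eight default conditions.

    Qualitative structure: the jam shows sour -> wet -> sweet dominance with
    liking peaking above 6 mid-tasting; crackers show dry/salty/wheat-like
    (plain) or sesame/burned (sesame) dominance with lower liking; pairings
    show spread attributes early and cracker attributes late, with an
    earlier liking peak.
    """
    spread_dwell = dict(dwell_mean_s=2.0)
    cracker_dwell = dict(dwell_mean_s=3.0)
    pair_dwell = dict(dwell_mean_s=2.5)

    profiles: dict[str, ConditionProfile] = {}

    profiles["strawberry"] = ConditionProfile(
        phases=(
            ((0.0, 0.30), _probs({"sour": 0.55, "wet": 0.25, "sweet": 0.10, "aromatic": 0.10})),
            ((0.30, 0.55), _probs({"wet": 0.45, "sweet": 0.30, "sour": 0.15, "smooth": 0.10})),
            ((0.55, 1.0), _probs({"sweet": 0.60, "wet": 0.20, "smooth": 0.10, "aromatic": 0.10})),
        ),
        hedonic_weights=_weights({"sweet": 7.5, "wet": 6.5}),
        **spread_dwell,
    )
    profiles["peanut"] = ConditionProfile(
        phases=(
            ((0.0, 0.35), _probs({"nutty": 0.45, "buttery": 0.25, "aromatic": 0.15, "salty": 0.15})),
            ((0.35, 0.70), _probs({"buttery": 0.35, "smooth": 0.30, "nutty": 0.20, "sweet": 0.15})),
            ((0.70, 1.0), _probs({"smooth": 0.40, "sweet": 0.30, "nutty": 0.20, "buttery": 0.10})),
        ),
        hedonic_weights=_weights({"nutty": 6.5, "buttery": 6.5}),
        **spread_dwell,
    )
    profiles["plain"] = ConditionProfile(
        phases=(
            ((0.0, 0.40), _probs({"dry": 0.50, "salty": 0.30, "wheat-like": 0.15, "burned": 0.05})),
            ((0.40, 0.75), _probs({"salty": 0.35, "wheat-like": 0.30, "dry": 0.25, "wet": 0.10})),
            ((0.75, 1.0), _probs({"wheat-like": 0.45, "wet": 0.25, "dry": 0.20, "salty": 0.10})),
        ),
        hedonic_weights=_weights({"salty": 5.5, "wheat-like": 5.5}),
        **cracker_dwell,
    )
    profiles["sesame"] = ConditionProfile(
        phases=(
            ((0.0, 0.40), _probs({"dry": 0.40, "sesame-like": 0.30, "burned": 0.15, "salty": 0.15})),
            ((0.40, 0.75), _probs({"sesame-like": 0.40, "nutty": 0.20, "wheat-like": 0.20, "dry": 0.20})),
            ((0.75, 1.0), _probs({"wheat-like": 0.35, "sesame-like": 0.25, "nutty": 0.20, "wet": 0.20})),
        ),
        hedonic_weights=_weights({"sesame-like": 6.0}),
        **cracker_dwell,
    )

    spread_early = {
        "peanut": {"nutty": 0.30, "buttery": 0.25, "smooth": 0.15, "sweet": 0.10, "salty": 0.10, "dry": 0.10},
        "strawberry": {"sour": 0.30, "sweet": 0.25, "wet": 0.25, "smooth": 0.10, "dry": 0.10},
    }
    spread_mid = {
        "peanut": {"buttery": 0.25, "smooth": 0.20, "sweet": 0.15, "nutty": 0.10, "salty": 0.15, "wheat-like": 0.15},
        "strawberry": {"sweet": 0.35, "wet": 0.20, "dry": 0.15, "salty": 0.15, "wheat-like": 0.15},
    }
    cracker_late = {
        "plain": {"wheat-like": 0.30, "dry": 0.25, "salty": 0.20, "sweet": 0.15, "wet": 0.10},
        "sesame": {"wheat-like": 0.25, "sesame-like": 0.25, "dry": 0.20, "sweet": 0.15, "nutty": 0.15},
    }
    for cracker in CRACKERS:
        for spread in SPREADS:
            profiles[f"{cracker}-{spread}"] = ConditionProfile(
                phases=(
                    ((0.0, 0.35), _probs(spread_early[spread])),
                    ((0.35, 0.65), _probs(spread_mid[spread])),
                    ((0.65, 1.0), _probs(cracker_late[cracker])),
                ),
                # mild hedonic enhancement for pairings: complementary textures
                hedonic_weights=_weights({"sweet": 7.5, "wet": 6.5, "dry": 4.5}),
                **pair_dwell,
            )
    return profiles


def validate_profiles(
    design: StudyDesign, profiles: Mapping[str, ConditionProfile]
) -> None:
    """Check that every design condition has a generative profile."""
    for cond in design.conditions:
        if cond.condition_id not in profiles:
            raise ConfigurationError(
                f"no profile for condition {cond.condition_id!r}"
            )


# ---------------------------------------------------------------------------
# config (de)serialization


def design_to_dict(design: StudyDesign) -> dict:
    return {
        "n_panelists": design.n_panelists,
        "n_repetitions": design.n_repetitions,
        "attributes": list(design.attributes),
        "conditions": [
            {"condition_id": c.condition_id, "cracker": c.cracker, "spread": c.spread}
            for c in design.conditions
        ],
        "mean_duration_s": dict(design.mean_duration_s),
        "duration_cv": design.duration_cv,
    }


def design_from_dict(d: Mapping) -> StudyDesign:
    return StudyDesign(
        n_panelists=int(d["n_panelists"]),
        n_repetitions=int(d["n_repetitions"]),
        conditions=tuple(
            FoodCondition(c["condition_id"], cracker=c.get("cracker"), spread=c.get("spread"))
            for c in d["conditions"]
        ),
        attributes=tuple(d.get("attributes", ATTRIBUTES)),
        mean_duration_s=dict(d.get("mean_duration_s", {"cracker": 20.0, "spread": 10.0})),
        duration_cv=float(d.get("duration_cv", 0.15)),
    )


def profile_to_dict(p: ConditionProfile) -> dict:
    return {
        "phases": [
            {"interval": [float(a), float(b)], "probs": np.asarray(v, float).tolist()}
            for (a, b), v in p.phases
        ],
        "hedonic_weights": np.asarray(p.hedonic_weights, float).tolist(),
        "dwell_mean_s": p.dwell_mean_s,
        "press_rate": p.press_rate,
        "noise_sd": p.noise_sd,
        "baseline_liking": p.baseline_liking,
        "tds_delay_frac": p.tds_delay_frac,
        "tl_delay_frac": p.tl_delay_frac,
    }


def profile_from_dict(d: Mapping) -> ConditionProfile:
    return ConditionProfile(
        phases=tuple(
            ((float(ph["interval"][0]), float(ph["interval"][1])), np.asarray(ph["probs"], float))
            for ph in d["phases"]
        ),
        hedonic_weights=np.asarray(d["hedonic_weights"], float),
        dwell_mean_s=float(d.get("dwell_mean_s", 2.5)),
        press_rate=float(d.get("press_rate", 12.0)),
        noise_sd=float(d.get("noise_sd", 0.8)),
        baseline_liking=float(d.get("baseline_liking", 5.0)),
        tds_delay_frac=float(d.get("tds_delay_frac", 0.05)),
        tl_delay_frac=float(d.get("tl_delay_frac", 0.10)),
    )


def save_config(path, design: StudyDesign, profiles: Mapping[str, ConditionProfile]) -> None:
    doc = {
        "design": design_to_dict(design),
        "profiles": {k: profile_to_dict(v) for k, v in profiles.items()},
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_config(path) -> tuple[StudyDesign, dict[str, ConditionProfile]]:
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    design = design_from_dict(doc["design"])
    profiles = {k: profile_from_dict(v) for k, v in doc["profiles"].items()}
    return design, profiles
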