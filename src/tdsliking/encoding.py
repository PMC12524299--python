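"""Model input assembly: 12 attribute channels plus auxiliary flag blocks.

Eight encoding configurations are supported, adding 0-7 constant binary
channels to the 12 dominance-proportion channels (total input dimension
12-19):

===============  ===  ==========================================================
name             aux  flags appended
===============  ===  ==========================================================
none              0   -
combo             1   combination (1 iff cracker-spread pairing)
cracker_spread    2   cracker, spread (both 1 for pairings)
exclusive3        3   cracker, spread, combination (mutually exclusive)
brand             4   premium, sesame, peanut, strawberry (ingredient presence)
brand_combo       5   brand block + combination flag
brand_cs          6   brand block + cracker/spread block (both-1 convention)
brand_all         7   brand block + exclusive cracker/spread/combination triple
===============  ===  ==========================================================

Flags are constant over the whole series: they encode sample context, not
dynamics. The plain cracker's brand flag is named "premium" after the
product brand.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .curves import CurveSet
from .design import ATTRIBUTES, ConfigurationError, FoodCondition

BRAND_FLAGS = ("premium", "sesame", "peanut", "strawberry")

#: encoding name -> (aux blocks, exclusive cracker/spread/combination triple?)
AUX_CONFIGS: dict[str, tuple[tuple[str, ...], bool]] = {
    "none": ((), False),
    "combo": (("combination",), False),
    "cracker_spread": (("cracker_spread",), False),
    "exclusive3": (("cracker_spread", "combination"), True),
    "brand": (("brand",), False),
    "brand_combo": (("brand", "combination"), False),
    "brand_cs": (("brand", "cracker_spread"), False),
    "brand_all": (("brand", "cracker_spread", "combination"), True),
}


@dataclass(frozen=True)
class EncodingConfig:
    """Which auxiliary flag block(s) to append to the attribute channels."""

    name: str = "none"

    def __post_init__(self) -> None:
        if self.name not in AUX_CONFIGS:
            raise ConfigurationError(
                f"unknown aux config {self.name!r}; choose from {sorted(AUX_CONFIGS)}"
            )

    @property
    def blocks(self) -> tuple[str, ...]:
        return AUX_CONFIGS[self.name][0]

    @property
    def exclusive_mode(self) -> bool:
        return AUX_CONFIGS[self.name][1]


@dataclass(frozen=True, eq=False)
class EncodedSeries:
    """Input matrix [n_points x (12 + aux_dim)] with channel names."""

    values: np.ndarray
    channel_names: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.values.ndim != 2 or self.values.shape[1] != len(self.channel_names):
            raise ValueError("values width must match channel names")

    @property
    def n_inputs(self) -> int:
        return self.values.shape[1]


def aux_dimension(cfg: EncodingConfig) -> int:
    """Number of auxiliary flag channels added by ``cfg`` (0-7)."""
    dim = 0
    for block in cfg.blocks:
        dim += {"combination": 1, "cracker_spread": 2, "brand": 4}[block]
    return dim


def flag_vector(condition: FoodCondition, cfg: EncodingConfig) -> tuple[np.ndarray, tuple[str, ...]]:
    """Constant flag values and names for one condition under one encoding."""
    values: list[float] = []
    names: list[str] = []
    for block in cfg.blocks:
        if block == "brand":
            presence = {
                "premium": condition.cracker == "plain",
                "sesame": condition.cracker == "sesame",
                "peanut": condition.spread == "peanut",
                "strawberry": condition.spread == "strawberry",
            }
            for b in BRAND_FLAGS:
                names.append(f"flag:{b}")
                values.append(1.0 if presence[b] else 0.0)
        elif block == "cracker_spread":
            if cfg.exclusive_mode:
                cracker = condition.cracker is not None and not condition.is_pairing
                spread = condition.spread is not None and not condition.is_pairing
            else:
                cracker = condition.cracker is not None
                spread = condition.spread is not None
            names += ["flag:cracker", "flag:spread"]
            values += [float(cracker), float(spread)]
        elif block == "combination":
            names.append("flag:combination")
            values.append(float(condition.is_pairing))
        else:  # pragma: no cover - guarded by EncodingConfig
            raise ConfigurationError(f"unknown aux block {block!r}")
    return np.array(values), tuple(names)


def encode(curve_set: CurveSet, condition: FoodCondition, cfg: EncodingConfig) -> EncodedSeries:
    """Assemble the model input series for one curve set.

    The attribute sub-matrix is the TDS dominance-proportion matrix
    transposed onto the grid, bit-exact; flag channels are constant.
    """
    if curve_set.condition_id != condition.condition_id:
        raise ConfigurationError(
            f"curve set is for {curve_set.condition_id!r}, not {condition.condition_id!r}"
        )
    flags, flag_names = flag_vector(condition, cfg)
    n_points = curve_set.grid.n_points
    attr = curve_set.tds.proportions.T  # [n_points x 12]
    if flags.size:
        values = np.hstack([attr, np.tile(flags, (n_points, 1))])
    else:
        values = attr.copy()
    return EncodedSeries(values, ATTRIBUTES + flag_names)
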