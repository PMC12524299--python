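"""Echo state network regression for temporal liking prediction.

The reservoir is a fixed random recurrent network with leaky-tanh dynamics

    x(t) = (1 - alpha) * x(t-1) + alpha * tanh(W x(t-1) + W_in u(t)),  x(0) = 0,

whose recurrent matrix ``W`` is drawn sparse-uniform and rescaled to a
target spectral radius; only the linear readout is trained, by ridge
regression on the pooled reservoir states of all training sequences
(bias column appended, penalty applied to all coefficients):

    W_out = Y X^T (X X^T + lambda I)^{-1}.

The model object follows the familiar build-then-fit pattern:
``TemporalLikingESN(train_sets, conditions, ...).fit()`` returns an
:class:`ESNResults` carrying the trained readout, training diagnostics,
``predict`` and ``summary``.

Sequences are short (one tasting, ~101 normalized-time steps) and all start
from the same quiescent state, so states are reset to zero between
sequences and no washout is discarded by default.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import scipy.linalg
import scipy.sparse

from .curves import CurveSet, TimeGrid, TLCurve
from .design import FoodCondition
from .encoding import EncodedSeries, EncodingConfig, aux_dimension, encode

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ESNParams:
    """Reservoir hyperparameters.

    Defaults are conventional echo-state settings: unit leak (plain tanh
    update), spectral radius 0.9 (echo-state property with margin), 10%
    recurrent density, dense inputs in [-1, 1], and a small ridge penalty.
    """

    n_neurons: int = 128
    spectral_radius: float = 0.9
    leak_rate: float = 1.0
    input_scaling: float = 1.0
    recurrent_density: float = 0.1
    input_density: float = 1.0
    ridge: float = 1e-6
    washout: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_neurons < 1:
            raise ValueError("n_neurons must be >= 1")
        if self.spectral_radius <= 0:
            raise ValueError("spectral_radius must be positive")
        if not (0 < self.leak_rate <= 1):
            raise ValueError("leak_rate must lie in (0, 1]")
        if self.input_scaling <= 0:
            raise ValueError("input_scaling must be positive")
        if not (0 < self.recurrent_density <= 1):
            raise ValueError("recurrent_density must lie in (0, 1]")
        if not (0 < self.input_density <= 1):
            raise ValueError("input_density must lie in (0, 1]")
        if self.ridge < 0:
            raise ValueError("ridge must be nonnegative")
        if self.washout < 0:
            raise ValueError("washout must be nonnegative")


def init_weights(
    params: ESNParams, n_inputs: int, seed: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Draw the fixed input and recurrent weight matrices.

    ``W`` entries are uniform in [-1, 1] at the requested density, then the
    whole matrix is rescaled so its largest eigenvalue magnitude equals the
    target spectral radius. A degenerate draw with zero spectral radius is
    redrawn with an incremented sub-seed (logged).
    """
    if n_inputs < 1:
        raise ValueError("n_inputs must be >= 1")
    seed = params.seed if seed is None else seed
    n = params.n_neurons
    for attempt in range(100):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(attempt,)))
        w = rng.uniform(-1.0, 1.0, size=(n, n))
        if params.recurrent_density < 1.0:
            w *= rng.random(size=(n, n)) < params.recurrent_density
        radius = float(np.max(np.abs(np.linalg.eigvals(w))))
        if radius > 0:
            w *= params.spectral_radius / radius
            break
        logger.warning("degenerate reservoir draw (spectral radius 0); redrawing")
    else:  # pragma: no cover - probability ~0
        raise RuntimeError("could not draw a non-degenerate reservoir")
    w_in = rng.uniform(-params.input_scaling, params.input_scaling, size=(n, n_inputs))
    if params.input_density < 1.0:
        w_in *= rng.random(size=(n, n_inputs)) < params.input_density
    return w_in, w


def run_reservoir(
    w_in: np.ndarray,
    w: np.ndarray,
    inputs: np.ndarray,
    leak_rate: float = 1.0,
    initial_state: np.ndarray | None = None,
) -> np.ndarray:
    """Drive the reservoir with one sequence [T x n_in] or a batch [S x T x n_in].

    Same-length sequences in a batch are advanced in lock-step (one matrix
    product per time step across the whole batch), which is what makes the
    full architecture sweep cheap. Returns states [T x n] or [S x T x n].
    """
    inputs = np.asarray(inputs, dtype=float)
    if not np.isfinite(inputs).all():
        raise ValueError("inputs contain NaN or infinite values")
    single = inputs.ndim == 2
    if single:
        inputs = inputs[None]
    s, t_len, n_in = inputs.shape
    if n_in != w_in.shape[1]:
        raise ValueError(f"input width {n_in} does not match W_in ({w_in.shape[1]})")
    n = w.shape[0]
    x = np.zeros((s, n)) if initial_state is None else np.broadcast_to(
        np.asarray(initial_state, float), (s, n)
    ).copy()
    states = np.empty((s, t_len, n))
    a = leak_rate
    for t in range(t_len):
        x = (1.0 - a) * x + a * np.tanh(x @ w.T + inputs[:, t] @ w_in.T)
        states[:, t] = x
    return states[0] if single else states


def fit_readout(
    states: np.ndarray, targets: np.ndarray, ridge: float
) -> np.ndarray:
    """Closed-form ridge readout on pooled bias-augmented states.

    ``states``: pooled rows [n_rows x n_neurons]; ``targets``: [n_rows].
    Returns ``w_out`` of length ``n_neurons + 1`` (bias last). The penalty
    applies to every coefficient including the bias.
    """
    states = np.asarray(states, float)
    targets = np.asarray(targets, float)
    if states.ndim != 2 or states.shape[0] != targets.shape[0]:
        raise ValueError("states and targets must have matching row counts")
    if states.shape[0] < 1:
        raise ValueError("need at least one training row")
    n_feat = states.shape[1] + 1
    if states.shape[0] < n_feat:
        logger.warning(
            "fewer pooled rows (%d) than readout coefficients (%d); "
            "the readout is under-determined", states.shape[0], n_feat,
        )
    x = np.hstack([states, np.ones((states.shape[0], 1))])
    gram = x.T @ x + ridge * np.eye(n_feat)
    try:
        return scipy.linalg.solve(gram, x.T @ targets, assume_a="pos")
    except (scipy.linalg.LinAlgError, np.linalg.LinAlgError) as exc:
        raise ValueError(
            "readout system is singular; use a ridge penalty > 0"
        ) from exc


def readout_predict(w_out: np.ndarray, states: np.ndarray) -> np.ndarray:
    """Apply the trained readout: y = W_out [x; 1] per state row."""
    return states @ w_out[:-1] + w_out[-1]


# ---------------------------------------------------------------------------
# model / results objects


class TemporalLikingESN:
    """Echo state network predicting a TL curve from encoded TDS inputs.

    Parameters
    ----------
    train_sets
        Training curve sets (typically bootstrap replicates of several
        conditions).
    conditions
        Mapping condition_id -> :class:`FoodCondition`, used to derive the
        auxiliary flags of each training set.
    encoding
        Auxiliary flag configuration name or :class:`EncodingConfig`.
    params
        Reservoir hyperparameters; keyword overrides (``n_neurons=...``)
        are applied on top.
    """

    def __init__(
        self,
        train_sets: Sequence[CurveSet],
        conditions: Mapping[str, FoodCondition],
        encoding: str | EncodingConfig = "none",
        params: ESNParams | None = None,
        **overrides,
    ) -> None:
        if not train_sets:
            raise ValueError("need at least one training curve set")
        self.encoding = (
            encoding if isinstance(encoding, EncodingConfig) else EncodingConfig(encoding)
        )
        self.params = replace(params or ESNParams(), **overrides)
        self.conditions = dict(conditions)
        self.train_sets = list(train_sets)
        grids = {cs.grid for cs in train_sets}
        if len(grids) != 1:
            raise ValueError("training curve sets must share one grid")
        self.grid: TimeGrid = grids.pop()
        self.n_inputs = len(self._encode(train_sets[0]).channel_names)
        self.w_in, self.w = init_weights(self.params, self.n_inputs)

    def _encode(self, cs: CurveSet) -> EncodedSeries:
        try:
            cond = self.conditions[cs.condition_id]
        except KeyError:
            raise ValueError(f"no FoodCondition known for {cs.condition_id!r}") from None
        return encode(cs, cond, self.encoding)

    def _input_batch(self, sets: Sequence[CurveSet]) -> np.ndarray:
        return np.stack([self._encode(cs).values for cs in sets])

    def states(self, sets: Sequence[CurveSet]) -> np.ndarray:
        """Reservoir state trajectories [S x T x n] for the given curve sets."""
        return run_reservoir(self.w_in, self.w, self._input_batch(sets), self.params.leak_rate)

    def fit(self, ridge: float | None = None) -> "ESNResults":
        """Train the readout on the pooled states of all training sequences."""
        lam = self.params.ridge if ridge is None else ridge
        states = self.states(self.train_sets)
        wo = self.params.washout
        pooled = states[:, wo:, :].reshape(-1, self.params.n_neurons)
        targets = np.concatenate([cs.tl.liking[wo:] for cs in self.train_sets])
        w_out = fit_readout(pooled, targets, lam)
        fitted = readout_predict(w_out, pooled)
        train_rmse = float(np.sqrt(np.mean((fitted - targets) ** 2)))
        return ESNResults(self, w_out, lam, train_rmse)


class ESNResults:
    """Trained readout plus diagnostics for a :class:`TemporalLikingESN`."""

    def __init__(
        self, model: TemporalLikingESN, w_out: np.ndarray, ridge: float, train_rmse: float
    ) -> None:
        self.model = model
        self.w_out = np.asarray(w_out, float)
        self.ridge = float(ridge)
        self.train_rmse = float(train_rmse)

    @property
    def n_train_sequences(self) -> int:
        return len(self.model.train_sets)

    def predict(self, curve_set: CurveSet, clip: bool = False) -> TLCurve | np.ndarray:
        """Predict the TL curve for one curve set's TDS input.

        Predictions are the raw readout by default; with ``clip=True`` they
        are clamped to the [0, 9] liking range and returned as a
        :class:`TLCurve`. Unclipped predictions may leave [0, 9] and are
        returned as a plain array.
        """
        states = self.model.states([curve_set])[0]
        y = readout_predict(self.w_out, states)
        if clip:
            return TLCurve(self.model.grid, np.clip(y, 0.0, 9.0))
        return y

    def predict_many(self, sets: Sequence[CurveSet], clip: bool = False) -> np.ndarray:
        """Raw predictions [S x T] for a batch of curve sets."""
        states = self.model.states(sets)
        y = readout_predict(self.w_out, states.reshape(-1, states.shape[-1]))
        y = y.reshape(states.shape[0], states.shape[1])
        return np.clip(y, 0.0, 9.0) if clip else y

    def summary(self) -> str:
        p = self.model.params
        lines = [
            "Temporal liking ESN results",
            "=" * 43,
            f"{'reservoir neurons':<28}{p.n_neurons}",
            f"{'spectral radius':<28}{p.spectral_radius}",
            f"{'leak rate':<28}{p.leak_rate}",
            f"{'recurrent density':<28}{p.recurrent_density}",
            f"{'input scaling':<28}{p.input_scaling}",
            f"{'ridge penalty':<28}{self.ridge:g}",
            f"{'aux encoding':<28}{self.model.encoding.name}"
            f" (+{aux_dimension(self.model.encoding)} flags)",
            f"{'input channels':<28}{self.model.n_inputs}",
            f"{'training sequences':<28}{self.n_train_sequences}",
            f"{'pooled training rows':<28}{self.n_train_sequences * (self.model.grid.n_points - p.washout)}",
            f"{'training RMSE':<28}{self.train_rmse:.4f}",
            "=" * 43,
        ]
        return "\n".join(lines)

    # -- serialization ------------------------------------------------------

    def save(self, path) -> None:
        """Write a single .npz archive: params, W_in, W (triplets), W_out."""
        coo = scipy.sparse.coo_matrix(self.model.w)
        np.savez_compressed(
            path,
            params=json.dumps(self.model.params.__dict__),
            encoding=self.model.encoding.name,
            n_inputs=self.model.n_inputs,
            n_points=self.model.grid.n_points,
            w_in=self.model.w_in,
            w_row=coo.row,
            w_col=coo.col,
            w_data=coo.data,
            w_out=self.w_out,
            ridge=self.ridge,
            train_rmse=self.train_rmse,
        )

    @staticmethod
    def load(path, conditions: Mapping[str, FoodCondition]) -> "ESNResults":
        with np.load(path, allow_pickle=False) as arc:
            params = ESNParams(**json.loads(str(arc["params"])))
            n = params.n_neurons
            w = scipy.sparse.coo_matrix(
                (arc["w_data"], (arc["w_row"], arc["w_col"])), shape=(n, n)
            ).toarray()
            model = TemporalLikingESN.__new__(TemporalLikingESN)
            model.params = params
            model.encoding = EncodingConfig(str(arc["encoding"]))
            model.conditions = dict(conditions)
            model.train_sets = []
            model.grid = TimeGrid(int(arc["n_points"]))
            model.n_inputs = int(arc["n_inputs"])
            model.w_in = arc["w_in"]
            model.w = w
            return ESNResults(model, arc["w_out"], float(arc["ridge"]), float(arc["train_rmse"]))
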