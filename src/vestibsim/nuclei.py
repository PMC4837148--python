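"""Nerve-nuclei interface: a single-layer perceptron producing eye velocity.

The vestibular nuclei sum the weighted firing rates of all afferents from both
sides, subtract a global offset (self-regulation / reliance on other cues) and
pass the result through a saturating hyperbolic tangent that lumps the
downstream oculomotor non-linearities:

    v = output_gain * tanh(input_scale * (sum_i w_i r_i - b))

where r_i is afferent i's firing rate expressed in units of the typical
spontaneous rate (``rate_scale``, 26.3 spikes/s by default).  Normalizing the
rates this way keeps the synaptic weights, the offset and the two learning
rates on a common, dimensionless scale so that the balance between offset
(heterosynaptic) and per-synapse (homosynaptic) adaptation is controlled by
the learning-rate ratio alone.

Left-side afferents carry positive weights and right-side afferents negative
ones: the push-pull organization by which an increased left canal rate drives
a positive (rightward) eye movement.  At the healthy resting point the
weighted sum equals the offset, so the eyes are still.
"""
from __future__ import annotations

import dataclasses
import json

import numpy as np
import pandas as pd

from ._seeding import spawn_rng
from .exceptions import ParameterError, StructuralError
from .population import LEFT, RIGHT, AfferentPopulation

#: Saturation level of the eye-velocity command, arbitrary units.
DEFAULT_OUTPUT_GAIN = 10.0
#: Argument scaling of the tanh; places the strongest studied stimulation
#: (25% amplitude + 100% rate comodulation at 200 pps) near 85% of saturation.
DEFAULT_INPUT_SCALE = 3.5e-4
#: Firing-rate normalization (spikes/s): the typical spontaneous rate.
DEFAULT_RATE_SCALE = 26.3


@dataclasses.dataclass
class SynapticState:
    """Synaptic weights and offset of the vestibular-nuclei perceptron."""

    weights: np.ndarray
    bias: float
    output_gain: float = DEFAULT_OUTPUT_GAIN
    input_scale: float = DEFAULT_INPUT_SCALE
    rate_scale: float = DEFAULT_RATE_SCALE

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 1:
            raise ParameterError("weights must be a 1-D vector")
        if not np.all(np.isfinite(self.weights)) or not np.isfinite(self.bias):
            raise ParameterError("weights and bias must be finite")
        if self.output_gain <= 0 or self.input_scale <= 0 or self.rate_scale <= 0:
            raise ParameterError("output_gain, input_scale and rate_scale must be > 0")

    def copy(self) -> "SynapticState":
        return SynapticState(
            weights=self.weights.copy(),
            bias=float(self.bias),
            output_gain=self.output_gain,
            input_scale=self.input_scale,
            rate_scale=self.rate_scale,
        )

    def drive(self, rates: np.ndarray) -> float:
        """Net drive sum_i w_i * (rate_i / rate_scale) - b."""
        rates = np.asarray(rates, dtype=float)
        if rates.shape[-1] != self.weights.shape[0]:
            raise StructuralError(
                f"rates length {rates.shape[-1]} does not match weight count {self.weights.shape[0]}"
            )
        return (rates / self.rate_scale) @ self.weights - self.bias

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "weights": self.weights.tolist(),
            "bias": float(self.bias),
            "output_gain": self.output_gain,
            "input_scale": self.input_scale,
            "rate_scale": self.rate_scale,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SynapticState":
        return cls(
            weights=np.asarray(d["weights"], dtype=float),
            bias=float(d["bias"]),
            output_gain=float(d.get("output_gain", DEFAULT_OUTPUT_GAIN)),
            input_scale=float(d.get("input_scale", DEFAULT_INPUT_SCALE)),
            rate_scale=float(d.get("rate_scale", DEFAULT_RATE_SCALE)),
        )

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load_json(cls, path) -> "SynapticState":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"id": np.arange(self.weights.size), "weight": self.weights})


def init_healthy_weights(
    pop: AfferentPopulation,
    mean_magnitude: float = 1.0,
    spread: float = 0.2,
    seed: int = 0,
    *,
    output_gain: float = DEFAULT_OUTPUT_GAIN,
    input_scale: float = DEFAULT_INPUT_SCALE,
    rate_scale: float = DEFAULT_RATE_SCALE,
) -> SynapticState:
    """Healthy synaptic organization: positive left, negative right weights.

    Weight magnitudes are normal around ``mean_magnitude`` with SD ``spread``
    (floored at a small positive value so no synapse starts inverted).  The
    offset is initialized to the expected weighted resting drive so that the
    resting eye velocity is exactly zero in expectation.
    """
    if mean_magnitude <= 0:
        raise ParameterError(f"mean_magnitude must be > 0, got {mean_magnitude}")
    if spread < 0:
        raise ParameterError(f"spread must be >= 0, got {spread}")
    rng = spawn_rng(seed)
    magnitudes = np.clip(rng.normal(mean_magnitude, spread, size=pop.n_total), 0.05 * mean_magnitude, None)
    signs = np.where(pop.side == LEFT, 1.0, -1.0)
    weights = signs * magnitudes
    bias = float((pop.mean_rest_rate / rate_scale) @ weights)
    return SynapticState(
        weights=weights,
        bias=bias,
        output_gain=output_gain,
        input_scale=input_scale,
        rate_scale=rate_scale,
    )


def eye_velocity(state: SynapticState, rates: np.ndarray) -> float:
    """Single-axis eye-velocity command for a vector of afferent rates.

    Odd-symmetric in the net drive and saturating at +/- output_gain.
    """
    return float(state.output_gain * np.tanh(state.input_scale * state.drive(rates)))


def normalized_output(state: SynapticState, rates: np.ndarray) -> float:
    """Eye velocity scaled to [-1, 1] (v / output_gain)."""
    return eye_velocity(state, rates) / state.output_gain


def delta_term(e: float, v_norm: float) -> float:
    """Back-propagated error with the Fahlman derivative substitute.

    delta = e * (1.1 - v_norm**2), evaluated on the normalized output so the
    multiplier stays in [0.1, 1.1] regardless of the output gain; the 0.1
    floor keeps learning alive when the output saturates.
    """
    if abs(v_norm) > 1.0 + 1e-9:
        raise ParameterError(f"normalized output must satisfy |v| <= 1, got {v_norm}")
    return e * (1.1 - v_norm * v_norm)
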