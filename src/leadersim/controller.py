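"""Genotype encoding and the feed-forward neural controller.

Each robot's controller is a 24-neuron feed-forward network: 18 inputs
(15 retina components R0,G0,B0..R4,G4,B4, two smell lines S0,S1, one
ground value G), 4 logistic hidden units, 2 logistic outputs driving the
left and right wheel.  All 86 free parameters (72 input-to-hidden
weights, 4 hidden biases, 8 hidden-to-output weights, 2 output biases)
are encoded as consecutive 8-bit groups of a 688-bit genotype; each byte
b in [0, 255] maps linearly to a weight w = -5 + 10*b/255 in [-5, +5].

Output units in (0, 1) map symmetrically to wheel speeds
(2*o - 1) * wheel_speed_max, so an output of 0.5 is a stopped wheel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from ._kernels import N_INPUTS, N_HIDDEN, N_OUTPUTS, N_PARAMS, OFF_B1, OFF_W2, OFF_B2

GENOTYPE_LENGTH = N_PARAMS * 8  # 688
WEIGHT_RANGE = (-5.0, 5.0)

_BIT_WEIGHTS = 2 ** np.arange(7, -1, -1)  # MSB first within each byte


class CorruptGenotypeError(ValueError):
    """Raised when a genotype does not have exactly 688 bits."""


@dataclass(frozen=True)
class NetworkParams:
    """Decoded controller parameters, every value in [-5, +5]."""

    input_hidden: np.ndarray   # (18, 4)
    hidden_bias: np.ndarray    # (4,)
    hidden_output: np.ndarray  # (4, 2)
    output_bias: np.ndarray    # (2,)

    def flat(self) -> np.ndarray:
        """The kernel-facing (86,) layout (see :func:`decode`)."""
        return np.concatenate([
            self.input_hidden.ravel(), self.hidden_bias,
            self.hidden_output.ravel(), self.output_bias,
        ])

    @classmethod
    def from_flat(cls, flat: np.ndarray) -> "NetworkParams":
        flat = np.asarray(flat, dtype=float)
        if flat.shape != (N_PARAMS,):
            raise ValueError(f"expected {N_PARAMS} parameters")
        return cls(
            input_hidden=flat[:OFF_B1].reshape(N_INPUTS, N_HIDDEN),
            hidden_bias=flat[OFF_B1:OFF_W2].copy(),
            hidden_output=flat[OFF_W2:OFF_B2].reshape(N_HIDDEN, N_OUTPUTS),
            output_bias=flat[OFF_B2:].copy(),
        )


def _check_bits(bits: np.ndarray) -> np.ndarray:
    bits = np.asarray(bits)
    if bits.shape != (GENOTYPE_LENGTH,):
        raise CorruptGenotypeError(
            f"genotype must have {GENOTYPE_LENGTH} bits, got shape {bits.shape}")
    return bits.astype(np.uint8)


def decode(bits: np.ndarray) -> NetworkParams:
    """Decode a 688-bit genotype into network parameters.

    Consecutive 8-bit groups (MSB first) are read as unsigned bytes and
    mapped linearly onto [-5, +5].  Parameter order: input-to-hidden
    weights row-major by input index, hidden biases, hidden-to-output
    weights row-major by hidden index, output biases.
    """
    bits = _check_bits(bits)
    ints = bits.reshape(N_PARAMS, 8) @ _BIT_WEIGHTS
    lo, hi = WEIGHT_RANGE
    flat = lo + (hi - lo) * ints / 255.0
    return NetworkParams.from_flat(flat)


def decode_flat(bits: np.ndarray) -> np.ndarray:
    """Decode straight to the (86,) flat layout used by the simulation kernel."""
    bits = _check_bits(bits)
    ints = bits.reshape(N_PARAMS, 8) @ _BIT_WEIGHTS
    lo, hi = WEIGHT_RANGE
    return lo + (hi - lo) * ints / 255.0


def encode(params: NetworkParams) -> np.ndarray:
    """Quantise parameters back to the nearest representable genotype."""
    lo, hi = WEIGHT_RANGE
    flat = np.clip(params.flat(), lo, hi)
    ints = np.rint((flat - lo) / (hi - lo) * 255.0).astype(np.uint8)
    bits = ((ints[:, None] >> np.arange(7, -1, -1)) & 1).astype(np.uint8)
    return bits.ravel()


def random_genotype(rng: np.random.Generator) -> np.ndarray:
    """I.i.d. uniform random 688-bit genotype."""
    return rng.integers(0, 2, size=GENOTYPE_LENGTH, dtype=np.uint8)


def forward(params: NetworkParams, inputs: np.ndarray,
            wheel_speed_max: float = 1.3) -> tuple[float, float]:
    """One controller pass: 18 sensor inputs -> (v_left, v_right).

    Logistic activations in both layers; outputs map symmetrically to
    [-wheel_speed_max, +wheel_speed_max].
    """
    inputs = np.asarray(inputs, dtype=float)
    if inputs.shape != (N_INPUTS,):
        raise ValueError(f"expected {N_INPUTS} inputs")
    return _kernels.forward_kernel(params.flat(), inputs, wheel_speed_max)
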