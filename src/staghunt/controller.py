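"""Genome decoding and the feed-forward hunter controller.

A hunter's behaviour is a fully connected sigmoid perceptron with one
hidden layer: sensory input (61 values including a constant bias) to
hidden neurons to two outputs, each output driving one wheel.  Genomes
are flat sequences of reals in [0, 1]; each gene maps linearly onto one
connection weight in [-w_max, +w_max].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .core import BodySpec, ControllerConfig

__all__ = [
    "ControllerArchitecture",
    "decode_genome",
    "forward",
    "wheels_from_outputs",
    "random_genome",
]


@dataclass(frozen=True)
class ControllerArchitecture:
    """Layer sizes and weight scaling of the controller network.

    The default 61-8-2 architecture implies 61*8 + (8+1)*2 = 506 weights:
    every input (proximity, camera, bias) feeds every hidden neuron, and
    the hidden layer plus its own bias feeds both wheel outputs.
    """

    n_inputs: int = 61
    n_hidden: int = 8
    n_outputs: int = 2
    w_max: float = 5.0

    @property
    def genome_length(self) -> int:
        return self.n_inputs * self.n_hidden + (self.n_hidden + 1) * self.n_outputs

    @classmethod
    def from_config(cls, body: BodySpec, controller: ControllerConfig
                    ) -> "ControllerArchitecture":
        n_inputs = body.n_proximity + 4 * body.n_camera_rays + 1
        return cls(n_inputs=n_inputs, n_hidden=controller.n_hidden,
                   n_outputs=2, w_max=controller.w_max)


def decode_genome(genome: np.ndarray,
                  arch: ControllerArchitecture = ControllerArchitecture()
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Map a [0, 1] genome onto the two weight matrices.

    Gene g becomes weight (2g - 1) * w_max.  Genes fill the
    input-to-hidden matrix row-major over (input, hidden), then the
    (hidden + bias)-to-output matrix row-major over (hidden+bias, output).

    Returns ``(w1, w2)`` with shapes (n_inputs, n_hidden) and
    (n_hidden + 1, n_outputs).
    """
    genome = np.asarray(genome, dtype=np.float64)
    if genome.ndim != 1 or genome.shape[0] != arch.genome_length:
        raise ValueError(
            f"genome length {genome.size} does not match architecture "
            f"{arch.n_inputs}-{arch.n_hidden}-{arch.n_outputs} "
            f"(expected {arch.genome_length})")
    w = (2.0 * genome - 1.0) * arch.w_max
    split = arch.n_inputs * arch.n_hidden
    w1 = w[:split].reshape(arch.n_inputs, arch.n_hidden)
    w2 = w[split:].reshape(arch.n_hidden + 1, arch.n_outputs)
    return np.ascontiguousarray(w1), np.ascontiguousarray(w2)


def forward(weights: tuple[np.ndarray, np.ndarray], input_vector: np.ndarray
            ) -> tuple[float, float]:
    """Run the network: sigmoid hidden layer, sigmoid outputs in (0, 1)."""
    w1, w2 = weights
    x = np.asarray(input_vector, dtype=np.float64)
    if x.shape[0] != w1.shape[0]:
        raise ValueError(f"input length {x.shape[0]} != n_inputs {w1.shape[0]}")
    hidden = np.empty(w1.shape[1])
    o = np.empty(w2.shape[1])
    _kernels.mlp_forward_kernel(x, np.ascontiguousarray(w1.T), w2, hidden, o)
    return float(o[0]), float(o[1])


def wheels_from_outputs(o1: float, o2: float, v_max: float = 2.0
                        ) -> tuple[float, float]:
    """Map outputs in (0, 1) onto signed wheel speeds in (-v_max, v_max).

    The signed mapping v = (2o - 1) v_max makes the all-zero-weight
    controller (outputs 0.5, 0.5) stationary and allows reversing.
    """
    return (2.0 * o1 - 1.0) * v_max, (2.0 * o2 - 1.0) * v_max


def random_genome(arch: ControllerArchitecture, rng: np.random.Generator
                  ) -> np.ndarray:
    """Uniform [0, 1] genome of the architecture's length."""
    return rng.random(arch.genome_length)
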