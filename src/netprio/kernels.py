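"""Random-walk graph kernels.

The one-step kernel of a symmetric nonnegative adjacency W is

    K = (a - 1) I + D^{-1/2} W D^{-1/2},   a > 1,

with D the diagonal degree matrix.  Because the symmetrically normalized
adjacency has spectrum in [-1, 1], choosing a >= 2 makes K positive
semidefinite.  The q-step kernel is the matrix power K^q: two genes are
similar if they are connected by walks of up to q steps, so larger q
probes the global topology of the network.
"""

from __future__ import annotations

import numpy as np

from .core import KernelMatrix, WeightedNetwork

__all__ = ["one_step_kernel", "q_step_kernel", "random_walk_kernel"]


def one_step_kernel(net: WeightedNetwork, a: float = 2.0) -> KernelMatrix:
    """One-step random-walk kernel of a network.

    Zero-degree genes get a zero D^{-1/2} entry: they stay kernel-isolated
    with self-similarity a - 1 and the normalization never divides by zero.
    """
    if a <= 1:
        raise ValueError(f"kernel parameter a must be > 1, got {a}")
    d = net.degrees()
    with np.errstate(divide="ignore"):
        dinv_sqrt = np.where(d > 0, d ** -0.5, 0.0)
    gram = dinv_sqrt[:, None] * net.weights * dinv_sqrt[None, :]
    gram[np.diag_indices_from(gram)] += a - 1.0
    return KernelMatrix(net.universe, gram, a=a, q=1)


def q_step_kernel(kernel: KernelMatrix, q: int) -> KernelMatrix:
    """Raise a one-step kernel to the q-th matrix power."""
    if q < 1:
        raise ValueError(f"step count q must be >= 1, got {q}")
    if kernel.q != 1:
        raise ValueError("q_step_kernel expects a one-step kernel as input")
    if q == 1:
        return kernel
    gram = np.linalg.matrix_power(kernel.gram, q)
    gram = (gram + gram.T) / 2.0  # remove float asymmetry from BLAS products
    return KernelMatrix(kernel.universe, gram, a=kernel.a, q=q)


def random_walk_kernel(net: WeightedNetwork, a: float = 2.0, q: int = 1) -> KernelMatrix:
    """Convenience: q-step random-walk kernel straight from a network."""
    return q_step_kernel(one_step_kernel(net, a=a), q)
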