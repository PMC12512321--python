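"""Permuted-block randomisation (building block 1).

Each block contains a fixed number of participants per arm (the design's
``allocation`` counts) in uniformly random order, so treatment totals stay
balanced throughout recruitment.  Arms are coded 0 = control, 1 = treatment.
"""

from __future__ import annotations

import numpy as np

from .design import DesignParameters

__all__ = ["simulate_randomisation"]


def simulate_randomisation(
    params: DesignParameters, rng: np.random.Generator
) -> np.ndarray:
    """Generate the sequential treatment-allocation list for ``params.n``.

    Whole blocks are generated up to at least ``n`` assignments and the
    sequence truncated to length ``n``, so a final partial block (when
    ``n`` is not a multiple of ``block_size``) is a truncated permuted
    block.  Within every block the arm counts equal ``params.allocation``
    and the ordering is a uniform random permutation, obtained by sorting
    per-block uniform draws.

    Returns
    -------
    numpy.ndarray
        Integer array of 0/1 arm indicators, length ``n``; participant
        ids are implicit as positions ``1..n``.
    """
    n, b = params.n, params.block_size
    n_blocks = -(-n // b)  # ceiling division
    template = np.repeat([0, 1], params.allocation)
    # rank of a uniform draw within its block is a uniform random permutation
    order = np.argsort(rng.random((n_blocks, b)), axis=1)
    assignments = template[order].reshape(-1)[:n]
    return assignments.astype(np.int64)
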