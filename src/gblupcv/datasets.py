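"""Small built-in datasets used in the documentation and tests."""

from __future__ import annotations

import numpy as np

from .types import GenotypeMatrix, PhenotypeVector, VarianceComponents

__all__ = ["toy_dataset"]


def toy_dataset() -> tuple[GenotypeMatrix, PhenotypeVector, VarianceComponents]:
    """A tiny hand-checkable dataset: 3 individuals, 5 markers.

    Variance components are sigma2_beta = 0.1, sigma2_e = 1 (lambda = 10)
    with sigma2_L = 1000 for the strategy-II mean device. Small enough
    that every leave-one-out quantity can be verified by hand, yet the
    genotypes are full row rank so both model formulations apply.
    """
    g = GenotypeMatrix(
        np.array([
            [1, 2, 1, 2, 2],
            [2, 1, 0, 1, 1],
            [0, 0, 2, 1, 2],
        ], dtype=float),
        individual_ids=["1", "2", "3"],
        marker_ids=["M1", "M2", "M3", "M4", "M5"],
    )
    y = PhenotypeVector(np.array([1.97, 2.12, -0.62]), g.individual_ids)
    vc = VarianceComponents(sigma2_beta=0.1, sigma2_e=1.0, sigma2_L=1000.0)
    return g, y, vc
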