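import numpy as np
import pytest

from gblupcv import (
    GenotypeMatrix,
    PhenotypeVector,
    VarianceComponents,
    toy_dataset,
)


@pytest.fixture
def toy():
    """The 3x5 hand-checkable dataset with lambda=10, sigma2_L=1000."""
    return toy_dataset()


def random_instance(rng, n=None, p=None, lam=10.0, require_polymorphic=True):
    """A random (GenotypeMatrix, PhenotypeVector, VarianceComponents) triple.

    Dosages are uniform over {0,1,2}; columns are redrawn until at least
    one is polymorphic so the genetic signal is nondegenerate.
    """
    n = int(rng.integers(3, 13)) if n is None else n
    p = int(rng.integers(1, 21)) if p is None else p
    for _ in range(100):
        d = rng.integers(0, 3, size=(n, p)).astype(float)
        if not require_polymorphic or np.ptp(d, axis=0).max() > 0:
            break
    g = GenotypeMatrix.from_array(d)
    y = PhenotypeVector(rng.standard_normal(n), g.individual_ids)
    vc = VarianceComponents.from_lambda(lam)
    return g, y, vc


def xxt_nonsingular(g, tol=1e-8):
    """True when the genomic relationship matrix XX' has full rank."""
    K = g.dosages @ g.dosages.T
    ev = np.linalg.eigvalsh(K)
    return ev.min() > tol * max(1.0, ev.max())
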