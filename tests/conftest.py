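import numpy as np
import pandas as pd
import pytest

from mitoarray import GenotypeMatrix, SimulationConfig, simulate_dataset
from mitoarray.datatypes import validate_markers


def make_markers(n, chromosome="1", start=1000, spacing=1000, gc=None, rng=None):
    """Small helper manifest with deterministic ids and positions."""
    rng = rng or np.random.default_rng(0)
    gc_vals = gc if gc is not None else rng.uniform(0.3, 0.7, size=n)
    return validate_markers(
        pd.DataFrame(
            dict(
                marker_id=[f"{chromosome}_{j:04d}" for j in range(n)],
                chromosome=chromosome,
                position=start + spacing * np.arange(n),
                ref_allele="A",
                alt_allele="G",
                gc_fraction=gc_vals,
            )
        )
    )


def random_genotypes(n_samples, n_markers, rng, maf_range=(0.1, 0.5), missing=0.0, chromosome="1"):
    p = rng.uniform(*maf_range, size=n_markers)
    calls = (rng.random((n_samples, n_markers, 2)) < p[None, :, None]).sum(axis=2).astype(float)
    if missing:
        calls[rng.random(calls.shape) < missing] = np.nan
    ids = [f"T{i:04d}" for i in range(n_samples)]
    return GenotypeMatrix(ids, make_markers(n_markers, chromosome=chromosome, rng=rng), calls)


@pytest.fixture(scope="session")
def small_dataset():
    """One small simulated cohort shared by read-only tests."""
    cfg = SimulationConfig(
        n_samples=80, n_auto_markers=300, n_mito_markers=40, n_chromosomes=2, seed=7
    )
    return simulate_dataset(cfg)
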