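import numpy as np
import pandas as pd
import pytest

from garrupop import simdata
from garrupop.vario import GenotypeMatrix, INFO_KEYS


def make_gm(dosages, positions=None, scaffold="scaffold_1", samples=None,
            scaffold_length=None, info=None, ref=None, alt=None):
    """Build a toy GenotypeMatrix from a (sites x samples) dosage array.

    -1 encodes missing.  Positions default to 100, 200, ... (1-based).
    """
    g = np.asarray(dosages, dtype=np.int8)
    n_sites, n_samples = g.shape
    if positions is None:
        positions = (np.arange(n_sites) + 1) * 100
    if samples is None:
        samples = [f"s{i}" for i in range(n_samples)]
    sites = pd.DataFrame(
        {
            "scaffold": scaffold,
            "pos": np.asarray(positions, dtype=int),
            "ref": ref if ref is not None else "A",
            "alt": alt if alt is not None else "G",
        }
    )
    for k in INFO_KEYS:
        sites[k] = info.get(k, np.nan) if info else np.nan
    if scaffold_length is None:
        scaffold_length = int(max(positions)) + 100
    return GenotypeMatrix(
        sites=sites,
        samples=list(samples),
        geno=g,
        scaffold_lengths={scaffold: scaffold_length},
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Default two-group cohort on two autosomes + Z + W (session cached)."""
    cfg = simdata.SimConfig(seed=101, n_scaffolds=2, scaffold_length=400_000)
    gm, samples, truth = simdata.simulate_cohort(cfg)
    return cfg, gm, samples, truth
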