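import numpy as np
import pytest

import tastecircuit as tc


@pytest.fixture(scope="session")
def taxonomy():
    return tc.RegionTaxonomy.default()


@pytest.fixture(scope="session")
def thalamus_taxonomy():
    """Taxonomy restricted to thalamus seeds and their targets, both hemispheres."""
    labels = ["thalamus", "dorsal_anterior_insula", "ventral_anterior_insula",
              "posterior_insula", "frontal_operculum"]
    regions = [tc.Region(lab, hemi, 30 + 5 * i)
               for hemi in ("left", "right") for i, lab in enumerate(labels)]
    return tc.RegionTaxonomy(regions)


@pytest.fixture(scope="session")
def chain_dataset():
    """Single-subject data from the chain X -> Y -> Z (beta = 0.7, n = 2000)."""
    rng = np.random.default_rng(11)
    x = rng.normal(size=2000)
    y = 0.7 * x + rng.normal(size=2000)
    z = 0.7 * y + rng.normal(size=2000)
    return np.column_stack([x, y, z]), ("X", "Y", "Z")


@pytest.fixture(scope="session")
def behavioral_targets():
    return {s.variable: s for s in tc.load_behavioral_targets()}
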