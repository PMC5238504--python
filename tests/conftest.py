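import numpy as np
import pandas as pd
import pytest

from tandemsite.synthetic_data import TABLE_PRESETS, AssayDesign, GroundTruth


@pytest.fixture
def m2_truth() -> GroundTruth:
    """Wild-type M2 ground truth (NMS tracer, steep retardation)."""
    return TABLE_PRESETS["M2_wt"]


@pytest.fixture
def noise_free_design() -> AssayDesign:
    return AssayDesign(noise_cv=0.0, n_experiments=1, rng_seed=0)


@pytest.fixture
def standard_design() -> AssayDesign:
    """The default assay: 4 experiments, duplicate wells, 3% noise."""
    return AssayDesign(rng_seed=2024)


def make_static_protein(n_residues: int = 12, atoms_per_res: int = 3,
                        seed: int = 0):
    """Atom table + single-frame coordinates for a fake protein.

    Each residue carries N/CA/C backbone atoms at random but fixed
    positions.
    """
    rng = np.random.default_rng(seed)
    names = ["N", "CA", "C"][:atoms_per_res]
    rows, coords = [], []
    for res in range(n_residues):
        base = rng.uniform(-20, 20, size=3)
        for j, name in enumerate(names):
            rows.append({"atom_id": len(rows), "name": name,
                         "residue_id": res + 1, "residue_name": "ALA",
                         "element": name[0]})
            coords.append(base + rng.normal(0, 1.0, size=3))
    return pd.DataFrame(rows), np.array(coords)


@pytest.fixture
def static_protein():
    return make_static_protein()
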