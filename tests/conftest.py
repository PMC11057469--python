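import warnings

import numpy as np
import pytest

from dsfbind import join_plate
from dsfbind.synthetic import ALBUMIN_PRESETS, SimBindingParams, simulate_plate


def grouped_curves(plate, pmap):
    """Sample + vehicle curves of a simulated plate, unmapped-well warnings muted."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        curves = join_plate(plate, pmap)
    return [c for c in curves if c.role in ("sample", "vehicle")]


@pytest.fixture
def hsa_single_site_plate():
    """Noiseless HSA plate with the published HSA–PFOA parameters."""
    protein = ALBUMIN_PRESETS["HSA"]
    binding = SimBindingParams(ligand="PFOA", kd_true_mM=0.79, dtm_max_true_C=13.0)
    conc = [0.0] + list(0.79 * np.logspace(-1, 1, 8))
    return simulate_plate(protein, binding, conc, n_replicates=3, noise_sd=0.0, seed=11)


@pytest.fixture
def bsa_biphasic_plate():
    """Noiseless biphasic BSA plate at the published cooperative slope."""
    protein = ALBUMIN_PRESETS["BSA"]
    binding = SimBindingParams(
        ligand="PFOS", mode="biphasic", hill_h=3.5, k_half_mM=0.6
    )
    conc = [0.0] + list(0.6 * np.logspace(-0.8, 0.8, 9))
    return simulate_plate(protein, binding, conc, n_replicates=3, noise_sd=0.0, seed=12)
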