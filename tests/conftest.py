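import numpy as np
import pytest

from obephys.synth import SynthCellParams, simulate_cell


@pytest.fixture(scope="session")
def clean_params():
    """A noise-free synthetic cell with default biology."""
    return SynthCellParams(noise_sd=0.0, seed=42)


@pytest.fixture(scope="session")
def clean_cell(clean_params):
    """Full protocol set for the noise-free cell (shared; treat as read-only)."""
    return simulate_cell(clean_params, "clean_cell", group="resident", treatment="sham")


@pytest.fixture(scope="session")
def recovery_cells():
    """50 synthetic cells with low access resistance and mild noise.

    The shared cohort for parameter-recovery scoring: Rs drawn in
    [5, 10] MOhm and 0.1 mV membrane noise.
    """
    rng = np.random.default_rng(123)
    cells = []
    for i in range(50):
        p = SynthCellParams(
            R_i_true=float(np.clip(rng.normal(870, 130), 400, 1500)),
            C_m_true=float(np.clip(rng.normal(20, 3), 10, 35)),
            R_s_true=float(rng.uniform(5, 10)),
            E_L=float(rng.normal(-64, 3)),
            spike_threshold_true=float(rng.normal(-34.5, 1.5)),
            spike_peak=float(rng.normal(37, 3)),
            ahp_conductance=float(np.clip(rng.normal(8, 2.5), 1, 16)),
            sag_conductance=float(np.clip(rng.normal(8.7, 1.2), 4, 14)),
            noise_sd=0.1,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        cells.append(simulate_cell(p, f"cell_{i:02d}"))
    return cells
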