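import numpy as np
import pytest

from vesiclebias import GenerativeConfig, simulate_dose_response, simulate_three_channel


@pytest.fixture
def noiseless_config():
    return GenerativeConfig(
        ligand_concentrations=(0.0, 0.1, 1.0, 10.0, 100.0, 1000.0),
        vesicles_per_concentration=20,
        K_L=10.0,
        K_resp=0.5,
        R_max=1.0,
        E0=0.2,
        cv_antibody=0.0,
        cv_ligand=0.0,
        seed=0,
    )


@pytest.fixture
def noiseless_table(noiseless_config):
    return simulate_dose_response(noiseless_config)


@pytest.fixture
def noisy_config():
    return GenerativeConfig(
        ligand_concentrations=(0.0, 0.5, 1.0, 2.0, 5.0, 10.0, 30.0, 100.0),
        vesicles_per_concentration=200,
        K_L=10.0,
        K_resp=0.5,
        R_max=1.0,
        E0=0.2,
        cv_antibody=0.2,
        seed=11,
    )


@pytest.fixture
def noisy_table(noisy_config):
    return simulate_dose_response(noisy_config)


@pytest.fixture
def three_channel_table():
    config = GenerativeConfig(
        ligand_concentrations=(0.0, 1.0, 3.0, 10.0, 30.0, 100.0, 1000.0, 10000.0),
        vesicles_per_concentration=250,
        K_L=10.0,
        K_resp=0.4,
        R_max=0.95,
        E0=0.15,
        cv_antibody=0.2,
        cv_ligand=0.2,
        ligand_gain=1.5,
        seed=7,
    )
    return config, simulate_three_channel(config)


def hill_sse_oracle(conc, response, e_top_bounds, ec50_bounds, n_grid=60, n_refine=6):
    """Brute-force grid-search minimizer of the slope-1 Hill SSE.

    Independent of any library optimizer: evaluates the SSE on a dense
    (EC50, E_top) grid and zooms around the best cell. EC50 is searched on
    a log grid.
    """
    conc = np.asarray(conc, dtype=float)
    response = np.asarray(response, dtype=float)
    lo_e, hi_e = e_top_bounds
    lo_c, hi_c = ec50_bounds
    best = None
    for _ in range(n_refine):
        e_grid = np.linspace(lo_e, hi_e, n_grid)
        c_grid = np.geomspace(lo_c, hi_c, n_grid)
        ee, cc = np.meshgrid(e_grid, c_grid, indexing="ij")
        pred = ee[:, :, None] * conc[None, None, :] / (conc[None, None, :] + cc[:, :, None])
        sse = np.sum((pred - response[None, None, :]) ** 2, axis=2)
        i, j = np.unravel_index(np.argmin(sse), sse.shape)
        best = (e_grid[i], c_grid[j])
        de = (hi_e - lo_e) / (n_grid - 1)
        lo_e, hi_e = best[0] - 2 * de, best[0] + 2 * de
        ratio = (hi_c / lo_c) ** (1.0 / (n_grid - 1))
        lo_c, hi_c = best[1] / ratio**2, best[1] * ratio**2
    return best  # (e_top, ec50)
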