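"""Synthetic single-vesicle dose-response data.

Generates per-vesicle fluorescence tables with the statistical structure the
downstream analysis assumes: Hill (slope 1) ligand binding, a hyperbolic
stimulus-response (transducer) map, an additive constitutive offset, and
multiplicative per-vesicle noise. Receptor-channel intensity is log-normal
across vesicles; noise on the response ratio and the ligand-channel ratio is
Gaussian with a configurable coefficient of variation, truncated so that
fluorescence values stay non-negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["GenerativeConfig", "simulate_dose_response", "simulate_three_channel"]

VESICLE_COLUMNS = [
    "vesicle_id",
    "experiment_id",
    "receptor_variant",
    "ligand",
    "ligand_conc_nM",
    "py_site",
    "receptor_fluor",
    "antibody_fluor",
    "ligand_fluor",
]


class ConfigError(ValueError):
    """A generative-config field violates its invariant."""


@dataclass(frozen=True)
class GenerativeConfig:
    """True parameters and noise settings of the synthetic model.

    Parameters
    ----------
    ligand_concentrations : sequence of float
        Nominal ligand doses in nM, each >= 0. Include 0 to generate the
        zero-ligand group used for the constitutive-signal estimate.
    vesicles_per_concentration : int
        Number of vesicles simulated at each dose.
    K_L : float
        Ligand-receptor dissociation constant in nM (> 0).
    K_resp : float
        Dimensionless transducer constant: the bound fraction producing
        half-maximal response (> 0).
    R_max : float
        Maximal response in ratio units (>= 0).
    E0 : float
        Constitutive (ligand-independent) response offset in ratio units.
    receptor_log_mean, receptor_log_sd : float
        Natural-log mean and sd of the per-vesicle receptor intensity.
    cv_antibody : float
        CV of the multiplicative noise on the per-vesicle response ratio.
    cv_ligand : float
        CV of the noise on the ligand-channel ratio (three-channel mode).
    ligand_gain : float
        Ligand-channel fluorescence per unit bound fraction per unit
        receptor fluorescence.
    seed : int
        RNG seed; identical config + seed gives byte-identical tables.
    """

    ligand_concentrations: Sequence[float] = field(default_factory=lambda: (0.0, 1.0, 3.0, 10.0, 30.0, 100.0))
    vesicles_per_concentration: int = 100
    K_L: float = 10.0
    K_resp: float = 0.5
    R_max: float = 1.0
    E0: float = 0.1
    receptor_log_mean: float = 5.0
    receptor_log_sd: float = 0.5
    cv_antibody: float = 0.2
    cv_ligand: float = 0.2
    ligand_gain: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        concs = np.asarray(self.ligand_concentrations, dtype=float)
        if concs.size == 0:
            raise ConfigError("ligand_concentrations: must be nonempty")
        if np.any(concs < 0) or not np.all(np.isfinite(concs)):
            raise ConfigError("ligand_concentrations: all concentrations must be finite and >= 0")
        if int(self.vesicles_per_concentration) < 1:
            raise ConfigError("vesicles_per_concentration: must be >= 1")
        if not self.K_L > 0:
            raise ConfigError("K_L: must be > 0")
        if not self.K_resp > 0:
            raise ConfigError("K_resp: must be > 0")
        if self.R_max < 0:
            raise ConfigError("R_max: must be >= 0")
        if self.E0 < 0:
            raise ConfigError("E0: must be >= 0")
        if self.cv_antibody < 0:
            raise ConfigError("cv_antibody: must be >= 0")
        if self.cv_ligand < 0:
            raise ConfigError("cv_ligand: must be >= 0")
        if self.receptor_log_sd < 0:
            raise ConfigError("receptor_log_sd: must be >= 0")

    def bound_fraction(self, conc: np.ndarray | float) -> np.ndarray | float:
        """Equilibrium bound fraction L/(L + K_L) at dose(s) ``conc``."""
        conc = np.asarray(conc, dtype=float)
        return conc / (conc + self.K_L)

    def true_ratio(self, conc: np.ndarray | float) -> np.ndarray | float:
        """Noise-free response ratio E0 + f R_max / (f + K_resp)."""
        f = np.asarray(self.bound_fraction(conc), dtype=float)
        return self.E0 + f * self.R_max / (f + self.K_resp)


def _simulate(config: GenerativeConfig, labels: dict | None, three_channel: bool) -> pd.DataFrame:
    labels = dict(labels or {})
    receptor_variant = labels.get("receptor_variant", "WT")
    ligand = labels.get("ligand", "EGF")
    py_site = labels.get("py_site", "Y1068")
    experiment_id = labels.get("experiment_id", "sim")

    rng = np.random.default_rng(config.seed)
    n = int(config.vesicles_per_concentration)
    frames = []
    vesicle_counter = 0
    for conc in config.ligand_concentrations:
        f_bound = float(config.bound_fraction(conc))
        r_true = float(config.true_ratio(conc))
        receptor = np.exp(rng.normal(config.receptor_log_mean, config.receptor_log_sd, size=n))
        noise = 1.0 + rng.normal(0.0, config.cv_antibody, size=n) if config.cv_antibody > 0 else np.ones(n)
        antibody = receptor * r_true * np.clip(noise, 0.0, None)
        if three_channel:
            lnoise = 1.0 + rng.normal(0.0, config.cv_ligand, size=n) if config.cv_ligand > 0 else np.ones(n)
            ligfluor = config.ligand_gain * receptor * f_bound * np.clip(lnoise, 0.0, None)
        else:
            ligfluor = np.full(n, np.nan)
        frames.append(
            pd.DataFrame(
                {
                    "vesicle_id": [f"v{vesicle_counter + i:06d}" for i in range(n)],
                    "experiment_id": experiment_id,
                    "receptor_variant": receptor_variant,
                    "ligand": ligand,
                    "ligand_conc_nM": float(conc),
                    "py_site": py_site,
                    "receptor_fluor": receptor,
                    "antibody_fluor": antibody,
                    "ligand_fluor": ligfluor,
                }
            )
        )
        vesicle_counter += n
    table = pd.concat(frames, ignore_index=True)
    table.attrs["seed"] = config.seed
    return table


def simulate_dose_response(config: GenerativeConfig, labels: dict | None = None) -> pd.DataFrame:
    """Simulate a two-channel (receptor + antibody) vesicle table.

    For each dose L and vesicle: ``f_bound = L/(L+K_L)``, true ratio
    ``r = E0 + f_bound*R_max/(f_bound+K_resp)``, receptor intensity drawn
    log-normal, and ``antibody = receptor * r * (1+eps)`` with ``eps``
    Gaussian (sd ``cv_antibody``) truncated so the product stays >= 0.
    Deterministic for a given seed.
    """
    return _simulate(config, labels, three_channel=False)


def simulate_three_channel(config: GenerativeConfig, labels: dict | None = None) -> pd.DataFrame:
    """Simulate a three-channel table including the ligand channel.

    Adds ``ligand_fluor = ligand_gain * receptor * f_bound * (1+eps')`` with
    ``eps'`` Gaussian (sd ``cv_ligand``), truncated at zero.
    """
    if not config.ligand_gain > 0:
        raise ConfigError("ligand_gain: must be > 0 for three-channel simulation")
    return _simulate(config, labels, three_channel=True)
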