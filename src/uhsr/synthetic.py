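"""Seeded TLC-like synthetic datasets with a known generating mechanism.

The generator emulates the structure of the real benchmark: three binary
mobile-phase systems (n-hexane/ethyl acetate, n-hexane/diethyl ether,
methanol/dichloromethane, with the methanol fraction capped at 0.10),
functional-group count vectors with the published marginal means, and Rf
produced by the reference governing equations:

    Psi     = psi_reference(solvent)                     (exact linear form)
    beta    = standardized fg_probe_linear(FG counts)    (printed probe weights)
    alpha   = standardized 0.5*DM + 0.5*NBen
    xi      = xi_reference(alpha, beta)
    Rf_true = rf_governing(Psi, xi)
    Rf_obs  = sigma(logit(Rf_true) + eps),  eps ~ N(0, noise_sd)

so every downstream stage can be tested against exact ground truth.  The
mechanism is the equations module's fixtures -- no second implementation
exists here.  The alpha ground truth is a simple affine composite of the
two distribution features rather than the interpretive alpha transcription,
keeping the oracle unambiguous.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .equations import fg_probe_linear, psi_reference, rf_governing, xi_reference
from .errors import ConfigError
from .features import (
    FG_NAMES, BENCHMARK_FG_MEANS, FGCounts, SoluteDescriptors, SolventComposition,
    TLCRecord, records_to_frame,
)
from .util import logit, sigmoid

__all__ = ["SynthConfig", "SynthDataset", "gen_solvents", "gen_solutes",
           "gen_dataset", "GRID_COMPOSITIONS", "BENCHMARK_FG_MEANS"]

#: Default composition grid: 17 binary compositions across the three
#: systems.  The real study's 17 compositions are not published; this grid
#: is a stand-in whose marginals approximate the published solvent means.
#: Rows are (Hex, EA, DCM, MeOH, Et2O).
GRID_COMPOSITIONS = np.array(
    [[1 - ea, ea, 0.0, 0.0, 0.0]
     for ea in (0.05, 0.10, 0.20, 1 / 3, 0.50, 0.75, 1.0)]
    + [[1 - e, 0.0, 0.0, 0.0, e] for e in (0.10, 0.25, 1 / 3, 0.50, 0.75)]
    + [[0.0, 0.0, 1 - m, m, 0.0] for m in (0.0, 0.01, 0.02, 0.05, 0.10)]
)

_SYSTEMS = ("hex_ea", "hex_et2o", "meoh_dcm")
# Mean minor-component fractions per system (uniform draws on [0, 2*mean]);
# chosen so the overall solvent marginals track the published means.
_MINOR_MEAN = {"hex_ea": 0.395, "hex_et2o": 0.338, "meoh_dcm": 0.0341}


@dataclass(frozen=True)
class SynthConfig:
    n_samples: int = 3000
    noise_sd: float = 0.05       # on the logit scale
    seed: int = 0
    solvent_mode: str = "grid"   # "grid" or "random"
    system_weights: tuple = (0.38, 0.21, 0.41)
    meoh_cap: float = 0.10
    fg_rates: dict = field(default_factory=lambda: dict(BENCHMARK_FG_MEANS))
    fg_cap: int = 3
    nben_probs: tuple = (0.10, 0.71, 0.16, 0.03)   # mean 1.12, sd ~ 0.60
    dm_mean: float = 1.34
    dm_sd: float = 0.74

    def __post_init__(self):
        if self.n_samples < 1:
            raise ConfigError("n_samples must be >= 1")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if any(v < 0 for v in self.fg_rates.values()):
            raise ConfigError("FG rates must be >= 0")
        if self.solvent_mode not in ("grid", "random"):
            raise ConfigError(f"unknown solvent_mode {self.solvent_mode!r}")
        if abs(sum(self.nben_probs) - 1.0) > 1e-9:
            raise ConfigError("nben_probs must sum to 1")


@dataclass
class SynthDataset:
    """Generated records plus the exact per-record ground truth."""

    records: list
    truth: pd.DataFrame          # id, psi, xi, alpha, beta, rf_true
    config: SynthConfig

    def to_frame(self) -> pd.DataFrame:
        return records_to_frame(self.records)

    def write(self, path, truth_path=None) -> None:
        self.to_frame().to_csv(path, index=False)
        if truth_path is not None:
            self.truth.to_csv(truth_path, index=False)


def gen_solvents(n: int, config: Optional[SynthConfig] = None,
                 rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """(n, 5) compositions in canonical solvent order, each summing to 1."""
    config = config or SynthConfig()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    if config.solvent_mode == "grid":
        reps = -(-n // len(GRID_COMPOSITIONS))
        comps = np.tile(GRID_COMPOSITIONS, (reps, 1))[:n]
        return comps[rng.permutation(n)]
    systems = rng.choice(len(_SYSTEMS), size=n, p=np.asarray(config.system_weights))
    out = np.zeros((n, 5))
    for i, s in enumerate(systems):
        name = _SYSTEMS[s]
        minor = rng.uniform(0.0, 2.0 * _MINOR_MEAN[name])
        if name == "hex_ea":
            out[i, 0], out[i, 1] = 1 - minor, minor
        elif name == "hex_et2o":
            out[i, 0], out[i, 4] = 1 - minor, minor
        else:
            minor = min(minor, config.meoh_cap)
            out[i, 2], out[i, 3] = 1 - minor, minor
    return out


def gen_solutes(n: int, config: Optional[SynthConfig] = None,
                rng: Optional[np.random.Generator] = None):
    """FG counts (truncated Poisson), ring counts and dipole moments.

    Returns (fg (n, 16) int array, n_ben (n,) int array, dm (n,) floats).
    """
    config = config or SynthConfig()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    lam = np.array([config.fg_rates[name] for name in FG_NAMES])
    fg = np.minimum(rng.poisson(lam, size=(n, 16)), config.fg_cap)
    n_ben = rng.choice(len(config.nben_probs), size=n,
                       p=np.asarray(config.nben_probs))
    dm = rng.normal(config.dm_mean, config.dm_sd, size=n)
    while np.any(dm < 0):  # truncate at zero by redrawing
        neg = dm < 0
        dm[neg] = rng.normal(config.dm_mean, config.dm_sd, size=int(neg.sum()))
    return fg, n_ben, dm


def _standardize(v: np.ndarray, what: str) -> np.ndarray:
    sd = v.std()
    if sd == 0.0:
        warnings.warn(f"degenerate configuration: zero-variance {what}")
        return v - v.mean()
    return (v - v.mean()) / sd


def gen_dataset(config: Optional[SynthConfig] = None) -> SynthDataset:
    """Generate a seeded dataset; truth is exactly regenerable from
    config + seed."""
    config = config or SynthConfig()
    rng = np.random.default_rng(config.seed)
    n = config.n_samples

    solvents = gen_solvents(n, config, rng)
    fg, n_ben, dm = gen_solutes(n, config, rng)

    psi = psi_reference(solvents)
    beta = _standardize(fg_probe_linear(fg.astype(float)), "FG probe index")
    alpha = _standardize(0.5 * dm + 0.5 * n_ben, "distribution composite")
    xi = xi_reference(alpha, beta)
    rf_true = rf_governing(psi, xi)
    if config.noise_sd > 0:
        # clip away from {0, 1} at float resolution so the logit is finite
        safe = np.clip(rf_true, 1e-12, 1 - 1e-12)
        rf_obs = sigmoid(logit(safe) + rng.normal(0.0, config.noise_sd, n))
    else:
        rf_obs = rf_true
    rf_obs = np.clip(rf_obs, 0.0, 1.0)

    records = []
    for i in range(n):
        records.append(TLCRecord(
            solvent=SolventComposition.from_array(solvents[i]),
            solute=SoluteDescriptors(
                fg=FGCounts.from_array(fg[i]),
                n_ben=int(n_ben[i]),
                dm=float(dm[i]),
            ),
            rf=float(rf_obs[i]),
            id=f"s{i:05d}",
        ))
    truth = pd.DataFrame({
        "id": [r.id for r in records],
        "psi": psi, "xi": xi, "alpha": alpha, "beta": beta,
        "rf_true": rf_true,
    })
    return SynthDataset(records=records, truth=truth, config=config)
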