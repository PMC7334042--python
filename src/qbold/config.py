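"""Default constants and YAML-backed configuration.

All sequence constants, physiological constants and empirical-relation
coefficients live here.  The defaults reproduce the standard 3 T grey-matter
ASE protocol used throughout the package (TE 74 ms, TR 3 s, 24 spin-echo
offsets from -28 ms to +64 ms in 4 ms steps, Hct 0.40, dchi0 0.264 ppm,
R2t 11.5 s^-1, R2b,true 5.29 s^-1, tD 4.51 ms).  A YAML file with the same
nesting can override any subset of values.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml

#: proton gyromagnetic ratio, rad s^-1 T^-1
GAMMA_PROTON = 2.675e8

#: susceptibility difference between fully deoxygenated blood and tissue
#: (dimensionless, 0.264 ppm)
DCHI0 = 0.264e-6

#: default asymptotic transition constant kappa = tc * delta_omega
KAPPA_DEFAULT = 1.76
#: alternative conventions selectable for comparison
KAPPA_YABLONSKIY = 1.5
KAPPA_HE = 1.0


def default_tau_schedule() -> tuple[float, ...]:
    """24 spin-echo displacements tau: -28 ms to +64 ms in 4 ms steps."""
    return tuple(np.round(np.arange(-28, 65, 4) * 1e-3, 6))


def reduced_tau_schedule() -> tuple[float, ...]:
    """11 spin-echo displacements tau: -16 ms to +64 ms in 8 ms steps."""
    return tuple(np.round(np.arange(-16, 65, 8) * 1e-3, 6))


@dataclass(frozen=True)
class ProtocolConfig:
    te: float = 0.074           # echo time, s
    tr: float = 3.0             # repetition time, s
    ti: float | None = None     # FLAIR inversion time, s (None: no inversion)
    b0: float = 3.0             # main field strength, T
    gamma: float = GAMMA_PROTON
    tau_schedule: tuple[float, ...] = field(default_factory=default_tau_schedule)


@dataclass(frozen=True)
class PhysiologyConfig:
    oef: float = 0.40           # oxygen extraction fraction
    dbv: float = 0.03           # deoxygenated blood volume fraction
    r2t: float = 11.5           # irreversible tissue transverse rate, s^-1
    s0: float = 1.0             # signal scale, arbitrary units
    hct: float = 0.40           # fractional haematocrit
    dchi0: float = DCHI0


@dataclass(frozen=True)
class BloodConfig:
    r2b_true: float = 5.29      # intrinsic R2 of fully oxygenated blood, s^-1
    td: float = 4.51e-3         # characteristic diffusion time, s
    t1b: float = 1.58           # venous blood T1 at 3 T, s
    nb: float = 0.775           # relative blood spin density
    # Empirical quadratic-in-OEF relations for the monoexponential blood model:
    #   R2b  = a0 + a1*Hct + (a2*Hct^2 + a3)*OEF^2
    #   R2b* = b0 + b1*Hct + (b2*Hct^2 + b3)*OEF^2
    r2b_coeffs: tuple[float, float, float, float] = (4.5, 16.4, 165.2, 55.7)
    r2bs_coeffs: tuple[float, float, float, float] = (10.2, -1.5, 136.9, -13.9)


@dataclass(frozen=True)
class PriorConfig:
    """Gaussian prior / initial-posterior settings for variational fitting.

    Means for R2' and DBV are the literature grey-matter values; the broad
    standard deviations (10^(3/2)) were selected as the least precise priors
    that still give stable estimates.  The amplitude parameter S0 carries a
    near-flat prior (mean 500, SD 10^3).  DBV is stored as a fraction, so the
    tabulated percent values are divided by 100.
    """

    mu0_r2p: float = 2.6
    sigma0_r2p: float = 10.0 ** 1.5
    mu0_dbv: float = 0.036
    sigma0_dbv: float = 10.0 ** 1.5 / 100.0
    mu0_s0: float = 500.0
    sigma0_s0: float = 1.0e3
    # OEF-parameterised fits (comparison experiments only)
    mu0_oef: float = 0.40
    sigma0_oef: float = 10.0 ** 1.5 / 100.0
    # near-uninformative Gamma prior on the noise precision (shape, scale)
    noise_shape: float = 1.0e-6
    noise_scale: float = 1.0e6


@dataclass(frozen=True)
class Config:
    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    physiology: PhysiologyConfig = field(default_factory=PhysiologyConfig)
    blood: BloodConfig = field(default_factory=BloodConfig)
    priors: PriorConfig = field(default_factory=PriorConfig)
    kappa: float = KAPPA_DEFAULT


def _merge(cls, defaults, overrides: dict):
    kwargs = {}
    for f in dataclasses.fields(cls):
        val = getattr(defaults, f.name)
        if f.name in overrides:
            ov = overrides[f.name]
            if dataclasses.is_dataclass(val) and isinstance(ov, dict):
                val = _merge(type(val), val, ov)
            elif isinstance(val, tuple) and isinstance(ov, (list, tuple)):
                val = tuple(ov)
            else:
                val = ov
        kwargs[f.name] = val
    return cls(**kwargs)


def load_config(path=None) -> Config:
    """Load a :class:`Config`, optionally overriding defaults from YAML.

    The YAML file mirrors the dataclass nesting, e.g.::

        physiology:
          hct: 0.34
        kappa: 1.5
    """
    cfg = Config()
    if path is None:
        return cfg
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return _merge(Config, cfg, data)
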