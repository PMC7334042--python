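"""Forward signal models for asymmetric spin echo (ASE) qBOLD.

The quantitative BOLD model treats venous vessels as randomly oriented,
infinitely long cylinders whose susceptibility offset is proportional to the
oxygen extraction fraction (OEF).  In the static dephasing regime the
extravascular (tissue) signal is

    St(t) = exp(-R2t*t) * exp(-DBV * I(dw*t)),
    I(x)  = int_0^1 (2+u) sqrt(1-u) / (3 u^2) * (1 - J0(1.5 x u)) du,

where J0 is the zero-order Bessel function, DBV the deoxygenated blood
volume fraction and dw the characteristic frequency at a vessel surface,

    dw = (4/3) pi * gamma * B0 * dchi0 * Hct * OEF.

Under ASE the refocusing pulse is displaced by tau/2, the readout stays at
TE, and the reversible dephasing becomes a function of |tau|; the integral is
replaced in fitting by its two asymptotic branches (quadratic below the
characteristic time tc = kappa/dw, linear-exponential above), which also
admit an equivalent parameterisation by R2' = DBV*dw.  An intravascular
(venous blood) compartment can be added, weighted by the apparent blood
volume zeta' = mb*nb*DBV; three blood models are available (monoexponential,
Fresnel "powder", and motional narrowing), and OEF can be recovered from
fitted (R2', DBV) by the inverse relation OEF = 3 R2' / (4 pi gamma B0 dchi0
Hct DBV).

All functions are pure and vectorised over ``tau``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import integrate, special

from .config import (DCHI0, GAMMA_PROTON, KAPPA_DEFAULT, BloodConfig,
                     default_tau_schedule)

__all__ = [
    "AcquisitionProtocol",
    "TissuePhysiology",
    "BloodCompartment",
    "characteristic_frequency",
    "transition_time",
    "static_dephasing_integral",
    "tissue_signal_analytic",
    "tissue_signal_analytic_ase",
    "tissue_signal_asymptotic",
    "tissue_signal_asymptotic_r2p",
    "loglinear_predict",
    "blood_relaxation_rates",
    "blood_signal_linear",
    "blood_signal_powder",
    "blood_signal_motional_narrowing",
    "apparent_dbv",
    "total_signal_2c",
    "oef_from_r2p",
]


# ----------------------------------------------------------------------------
# domain types
# ----------------------------------------------------------------------------

@dataclass(frozen=True)
class AcquisitionProtocol:
    """Sequence constants and the spin-echo displacement schedule.

    Parameters
    ----------
    te, tr : float
        Echo time and repetition time, s.
    ti : float or None
        FLAIR inversion time, s; ``None`` for a non-inversion acquisition.
    b0 : float
        Field strength, T.
    gamma : float
        Proton gyromagnetic ratio, rad s^-1 T^-1.
    tau_schedule : tuple of float
        Strictly increasing spin-echo displacements tau, s, all with
        ``|tau| < te``.
    """

    te: float = 0.074
    tr: float = 3.0
    ti: float | None = None
    b0: float = 3.0
    gamma: float = GAMMA_PROTON
    tau_schedule: tuple = ()

    def __post_init__(self):
        if self.te <= 0:
            raise ValueError("TE must be positive")
        if self.b0 <= 0:
            raise ValueError("B0 must be positive")
        if not self.tau_schedule:
            object.__setattr__(self, "tau_schedule", default_tau_schedule())
        tau = np.asarray(self.tau_schedule, dtype=float)
        if np.any(np.abs(tau) >= self.te):
            raise ValueError("every |tau| must be smaller than TE")
        if tau.size > 1 and np.any(np.diff(tau) <= 0):
            raise ValueError("tau_schedule must be strictly increasing")

    @property
    def tau(self) -> np.ndarray:
        return np.asarray(self.tau_schedule, dtype=float)


@dataclass(frozen=True)
class TissuePhysiology:
    """Voxel parameters of the tissue compartment."""

    oef: float = 0.40
    dbv: float = 0.03
    r2t: float = 11.5
    s0: float = 1.0
    hct: float = 0.40
    dchi0: float = DCHI0

    def __post_init__(self):
        for name in ("oef", "dbv", "hct"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.r2t < 0:
            raise ValueError("r2t must be non-negative")
        if self.s0 <= 0:
            raise ValueError("s0 must be positive")


@dataclass(frozen=True)
class BloodCompartment:
    """Venous blood compartment parameters.

    ``mb`` (steady-state blood magnetisation) may be supplied directly; when
    ``None`` it is derived from the blood T1 and the sequence timing:
    inversion-recovery steady state ``1 - 2 exp(-TI/T1b) + exp(-TR/T1b)``
    when the protocol has a FLAIR inversion, else the saturation steady
    state ``1 - exp(-TR/T1b)``.
    """

    r2b_true: float = 5.29
    td: float = 4.51e-3
    t1b: float = 1.58
    nb: float = 0.775
    mb: float | None = None
    zeta_apparent: float | None = None

    def __post_init__(self):
        if self.r2b_true < 0:
            raise ValueError("r2b_true must be non-negative")
        if self.td <= 0:
            raise ValueError("td must be positive")
        if self.zeta_apparent is not None and not 0 <= self.zeta_apparent <= 1:
            raise ValueError("zeta_apparent must lie in [0, 1]")

    def magnetisation(self, proto: AcquisitionProtocol) -> float:
        """Steady-state longitudinal blood magnetisation mb."""
        if self.mb is not None:
            return self.mb
        if proto.ti is not None:
            return 1.0 - 2.0 * np.exp(-proto.ti / self.t1b) + np.exp(-proto.tr / self.t1b)
        return 1.0 - np.exp(-proto.tr / self.t1b)

    def zeta(self, dbv: float, proto: AcquisitionProtocol) -> float:
        """Apparent DBV zeta' = mb*nb*DBV (or the supplied override)."""
        if self.zeta_apparent is not None:
            return self.zeta_apparent
        return apparent_dbv(dbv, self.magnetisation(proto), self.nb)

    @classmethod
    def from_config(cls, cfg: BloodConfig, **kw) -> "BloodCompartment":
        return cls(r2b_true=cfg.r2b_true, td=cfg.td, t1b=cfg.t1b, nb=cfg.nb, **kw)


# ----------------------------------------------------------------------------
# characteristic quantities
# ----------------------------------------------------------------------------

def characteristic_frequency(phys: TissuePhysiology,
                             proto: AcquisitionProtocol) -> float:
    """Characteristic frequency dw = (4/3) pi gamma B0 dchi0 Hct OEF, rad/s."""
    return (4.0 / 3.0) * np.pi * proto.gamma * proto.b0 * phys.dchi0 \
        * phys.hct * phys.oef


def transition_time(phys: TissuePhysiology, proto: AcquisitionProtocol,
                    kappa: float = KAPPA_DEFAULT) -> float:
    """Characteristic time tc = kappa/dw separating the asymptotic regimes."""
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    dw = characteristic_frequency(phys, proto)
    return np.inf if dw == 0 else kappa / dw


def oef_from_r2p(r2p, dbv, hct, proto: AcquisitionProtocol,
                 dchi0: float = DCHI0):
    """OEF = 3 R2' / (4 pi gamma B0 dchi0 Hct DBV).

    Vectorised; DBV <= 0 yields NaN (reported as missing, never infinity).
    """
    r2p = np.asarray(r2p, dtype=float)
    dbv = np.asarray(dbv, dtype=float)
    denom = 4.0 * np.pi * proto.gamma * proto.b0 * dchi0 * hct * dbv
    with np.errstate(divide="ignore", invalid="ignore"):
        oef = np.where(dbv > 0, 3.0 * r2p / np.where(dbv > 0, denom, 1.0), np.nan)
    if oef.ndim == 0:
        return float(oef)
    return oef


# ----------------------------------------------------------------------------
# analytic tissue model
# ----------------------------------------------------------------------------

_INTEGRAL_CACHE: dict[float, float] = {0.0: 0.0}


def _integrand(u: float, x: float) -> float:
    z = 1.5 * x * u
    if z < 1e-4:  # series avoids cancellation in 1 - J0(z) for tiny z
        bessel_term = z * z / 4.0 - z ** 4 / 64.0
    else:
        bessel_term = 1.0 - special.j0(z)
    return (2.0 + u) * np.sqrt(1.0 - u) / (3.0 * u * u) * bessel_term


def static_dephasing_integral(x):
    """I(x) = int_0^1 (2+u) sqrt(1-u)/(3u^2) (1 - J0(1.5 x u)) du.

    The integrand is finite at u -> 0 (it tends to 3 x^2 / 8).  Values are
    cached per ``x``; array input is evaluated per unique element.

    Asymptotics: I(x) -> 0.3 x^2 for small x and I(x) -> x - 1 for large x.
    """
    x_arr = np.atleast_1d(np.asarray(x, dtype=float))
    out = np.empty_like(x_arr)
    for i, xi in enumerate(x_arr.flat):
        xi = abs(float(xi))
        if xi not in _INTEGRAL_CACHE:
            val, err = integrate.quad(_integrand, 0.0, 1.0, args=(xi,),
                                      epsabs=1e-12, epsrel=1e-10, limit=200)
            if not np.isfinite(val) or (abs(val) > 1e-10 and err > 1e-8 * abs(val)):
                raise RuntimeError(
                    f"static dephasing quadrature did not converge at x={xi}: "
                    f"value={val}, abserr={err}")
            _INTEGRAL_CACHE[xi] = val
        out.flat[i] = _INTEGRAL_CACHE[abs(float(x_arr.flat[i]))]
    if np.ndim(x) == 0:
        return float(out[0])
    return out.reshape(np.shape(x))


def tissue_signal_analytic(phys: TissuePhysiology, proto: AcquisitionProtocol,
                           t):
    """Free-dephasing tissue signal fraction exp(-R2t t) exp(-DBV I(dw t)).

    ``t`` is the time since the effective dephasing onset (t >= 0).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    dw = characteristic_frequency(phys, proto)
    return np.exp(-phys.r2t * t) * np.exp(-phys.dbv * static_dephasing_integral(dw * t))


def tissue_signal_analytic_ase(phys: TissuePhysiology,
                               proto: AcquisitionProtocol, tau):
    """Analytic tissue signal mapped to the ASE experiment.

    Irreversible decay acts over the fixed TE while the reversible static
    dephasing acts over the net displacement |tau|:

        St(tau) = S0 exp(-R2t TE) exp(-DBV I(dw |tau|)).
    """
    tau = np.asarray(tau, dtype=float)
    dw = characteristic_frequency(phys, proto)
    return phys.s0 * np.exp(-phys.r2t * proto.te) \
        * np.exp(-phys.dbv * static_dephasing_integral(dw * np.abs(tau)))


# ----------------------------------------------------------------------------
# asymptotic (fitting) tissue model
# ----------------------------------------------------------------------------

def tissue_signal_asymptotic_r2p(r2p, dbv, s0, r2t,
                                 proto: AcquisitionProtocol, tau,
                                 kappa: float = KAPPA_DEFAULT):
    """Asymptotic one-compartment tissue model, R2' parameterisation.

        St(tau) = S0 exp(-R2t TE) * exp(-3/10 (R2' tau)^2 / DBV)   |tau| <  tc
                = S0 exp(-R2t TE) * exp(DBV - R2' |tau|)           |tau| >= tc

    with tc = kappa * DBV / R2' (equality assigned to the long branch so the
    fitted long-tau regime stays contiguous).  DBV = 0 (hence R2' = 0) makes
    tc infinite and returns the pure spin-echo decay.
    """
    tau = np.asarray(tau, dtype=float)
    abs_tau = np.abs(tau)
    base = s0 * np.exp(-r2t * proto.te)
    if r2p == 0 or dbv == 0:
        if r2p == 0:
            return base * np.ones_like(tau) if tau.ndim else float(base)
        # r2p > 0 with dbv == 0 is unphysical for this model
        raise ValueError("DBV must be positive when R2' > 0")
    tc = kappa * dbv / r2p
    short = np.exp(-0.3 * (r2p * tau) ** 2 / dbv)
    long_ = np.exp(dbv - r2p * abs_tau)
    out = base * np.where(abs_tau < tc, short, long_)
    return float(out) if np.ndim(tau) == 0 else out


def tissue_signal_asymptotic(phys: TissuePhysiology,
                             proto: AcquisitionProtocol, tau,
                             parameterisation: str = "OEF",
                             kappa: float = KAPPA_DEFAULT):
    """Asymptotic tissue model in either the OEF or the R2' parameterisation.

    Both give identical values when R2' = DBV*dw; they differ only in which
    quantity is treated as the free parameter.
    """
    if parameterisation not in ("OEF", "R2p"):
        raise ValueError("parameterisation must be 'OEF' or 'R2p'")
    tau = np.asarray(tau, dtype=float)
    dw = characteristic_frequency(phys, proto)
    base = phys.s0 * np.exp(-phys.r2t * proto.te)
    if parameterisation == "R2p":
        r2p = phys.dbv * dw
        return tissue_signal_asymptotic_r2p(r2p, phys.dbv, phys.s0, phys.r2t,
                                            proto, tau, kappa)
    if dw == 0:  # tc infinite: always the (vanishing) short branch
        out = base * np.ones_like(tau)
        return float(out) if np.ndim(tau) == 0 else out
    tc = kappa / dw
    abs_tau = np.abs(tau)
    short = np.exp(-0.3 * phys.dbv * (dw * tau) ** 2)
    long_ = np.exp(phys.dbv - phys.dbv * dw * abs_tau)
    out = base * np.where(abs_tau < tc, short, long_)
    return float(out) if np.ndim(tau) == 0 else out


def loglinear_predict(r2p, dbv, sse_t, tau):
    """Log-linear (sqBOLD) model: ln St(tau) = -R2' tau + ln(SSEt) + DBV.

    Valid in the long-tau regime; at tau = 0 it returns ln(SSEt) only when
    DBV = 0 (the measured spin-echo point is handled separately by fitters).
    """
    tau = np.asarray(tau, dtype=float)
    out = -r2p * tau + np.log(sse_t) + dbv
    return float(out) if np.ndim(tau) == 0 else out


# ----------------------------------------------------------------------------
# intravascular (blood) models
# ----------------------------------------------------------------------------

def blood_relaxation_rates(oef, hct, cfg: BloodConfig | None = None):
    """Empirical (R2b, R2b*) of venous blood as quadratics in OEF.

    Coefficients are configuration values; the defaults are the literature
    3 T relations (see :class:`qbold.config.BloodConfig`).
    """
    cfg = cfg or BloodConfig()
    a0, a1, a2, a3 = cfg.r2b_coeffs
    b0, b1, b2, b3 = cfg.r2bs_coeffs
    r2b = a0 + a1 * hct + (a2 * hct ** 2 + a3) * oef ** 2
    r2bs = b0 + b1 * hct + (b2 * hct ** 2 + b3) * oef ** 2
    return r2b, r2bs


def blood_signal_linear(oef, hct, proto: AcquisitionProtocol, tau,
                        cfg: BloodConfig | None = None):
    """Monoexponential blood model exp(-R2b TE) exp(-R2b* |tau|)."""
    tau = np.asarray(tau, dtype=float)
    r2b, r2bs = blood_relaxation_rates(oef, hct, cfg)
    out = np.exp(-r2b * proto.te) * np.exp(-r2bs * np.abs(tau))
    return float(out) if np.ndim(tau) == 0 else out


def blood_signal_powder(oef, hct, proto: AcquisitionProtocol, tau,
                        cfg: BloodConfig | None = None,
                        dchi0: float = DCHI0):
    """Fresnel ("powder") blood model magnitude.

        |Sb(tau)| = exp(-R2b TE) * |C(eta) - i S(eta)| / eta,
        eta = sqrt(3 dw |tau| / pi),

    with C, S the Fresnel integrals (scipy convention) and dw the
    characteristic frequency of the blood compartment.  The printed phase
    factor exp(i dw tau / 2) has unit modulus and is discarded (magnitude MR
    signal).  eta -> 0 is the analytic limit 1.
    """
    tau = np.asarray(tau, dtype=float)
    r2b, _ = blood_relaxation_rates(oef, hct, cfg)
    phys = TissuePhysiology(oef=oef, hct=hct, dchi0=dchi0)
    dw = characteristic_frequency(phys, proto)
    eta = np.sqrt(3.0 * dw * np.abs(tau) / np.pi)
    s_fres, c_fres = special.fresnel(eta)
    with np.errstate(divide="ignore", invalid="ignore"):
        mod = np.where(eta > 1e-12,
                       np.hypot(c_fres, s_fres) / np.where(eta > 1e-12, eta, 1.0),
                       1.0)
    out = np.exp(-r2b * proto.te) * mod
    return float(out) if np.ndim(tau) == 0 else out


def mean_square_field(oef, hct, b0, dchi0: float = DCHI0):
    """G0 = (4/45) Hct (1-Hct) (4 pi B0 OEF dchi0)^2, T^2."""
    return (4.0 / 45.0) * hct * (1.0 - hct) \
        * (4.0 * np.pi * b0 * oef * dchi0) ** 2


def blood_signal_motional_narrowing(oef, hct, blood: BloodCompartment,
                                    proto: AcquisitionProtocol, tau,
                                    dchi0: float = DCHI0):
    """Motional-narrowing blood model.

    Spins in plasma diffuse past red blood cells quickly relative to TE, so
    intravascular dephasing is motionally averaged.  Under the Gaussian phase
    approximation with diffusion time tD and mean-square field G0,

        Sb(tau) = exp(-R2b,true TE) * exp(-(gamma^2 G0 tD^2 / 2) * B(tau)),
        B(tau)  = TE/tD + sqrt(1/4 + TE/tD) + 3/2
                  - 2 sqrt(1/4 + (TE+tau)/(2 tD))
                  - 2 sqrt(1/4 + (TE-tau)/(2 tD)),

    which is even in tau and requires |tau| <= TE.  OEF = 0 gives G0 = 0 and
    the pure exp(-R2b,true TE) decay.
    """
    if not 0.0 < hct < 1.0:
        raise ValueError("Hct must lie strictly in (0, 1)")
    tau = np.asarray(tau, dtype=float)
    if np.any(proto.te - np.abs(tau) < 0):
        raise ValueError("|tau| must not exceed TE for the motional-"
                         "narrowing blood model")
    g0 = mean_square_field(oef, hct, proto.b0, dchi0)
    td = blood.td
    te = proto.te
    bracket = (te / td + np.sqrt(0.25 + te / td) + 1.5
               - 2.0 * np.sqrt(0.25 + (te + tau) / (2.0 * td))
               - 2.0 * np.sqrt(0.25 + (te - tau) / (2.0 * td)))
    out = np.exp(-blood.r2b_true * te) \
        * np.exp(-0.5 * proto.gamma ** 2 * g0 * td ** 2 * bracket)
    return float(out) if np.ndim(tau) == 0 else out


def apparent_dbv(dbv, mb, nb):
    """Apparent (magnetisation-weighted) DBV, zeta' = mb * nb * DBV."""
    for name, v in (("dbv", dbv), ("mb", mb), ("nb", nb)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    return mb * nb * dbv


_BLOOD_MODELS = ("linear", "powder", "mn")


def blood_signal(oef, hct, blood: BloodCompartment,
                 proto: AcquisitionProtocol, tau, blood_model: str = "mn",
                 dchi0: float = DCHI0):
    """Dispatch to one of the three intravascular models."""
    if blood_model == "mn":
        return blood_signal_motional_narrowing(oef, hct, blood, proto, tau,
                                               dchi0)
    if blood_model == "linear":
        return blood_signal_linear(oef, hct, proto, tau)
    if blood_model == "powder":
        return blood_signal_powder(oef, hct, proto, tau, dchi0=dchi0)
    raise ValueError(f"unknown blood model {blood_model!r}; "
                     f"choose from {_BLOOD_MODELS}")


def total_signal_2c(phys: TissuePhysiology, blood: BloodCompartment,
                    proto: AcquisitionProtocol, tau,
                    blood_model: str = "mn", tissue: str = "asymptotic",
                    kappa: float = KAPPA_DEFAULT):
    """Two-compartment total signal S = S0 (zeta' Sb + (1 - zeta') St).

    ``tissue`` selects the asymptotic tissue model (fitting) or the analytic
    model (simulation ground truth); both St and Sb here are signal
    fractions, scaled once by S0.
    """
    zeta = blood.zeta(phys.dbv, proto)
    norm = replace(phys, s0=1.0)
    if tissue == "asymptotic":
        st = tissue_signal_asymptotic(norm, proto, tau, kappa=kappa)
    elif tissue == "analytic":
        st = tissue_signal_analytic_ase(norm, proto, tau)
    else:
        raise ValueError("tissue must be 'asymptotic' or 'analytic'")
    sb = blood_signal(phys.oef, phys.hct, blood, proto, tau, blood_model,
                      phys.dchi0)
    return phys.s0 * (zeta * sb + (1.0 - zeta) * st)
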