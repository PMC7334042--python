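"""Least-squares estimation of qBOLD parameters.

Two estimators:

* :func:`fit_loglinear` — the streamlined (sqBOLD) procedure: ordinary
  least squares of ln S on tau over the long-tau points gives R2' (negative
  slope); DBV is the intercept minus the log of the measured spin-echo
  amplitude; OEF follows from R2'/DBV.
* :func:`fit_nonlinear_ls` — bounded non-linear least squares of the full
  one- or two-compartment asymptotic model over the whole tau schedule,
  initialised from the log-linear estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .config import KAPPA_DEFAULT
from .models import (AcquisitionProtocol, BloodCompartment, TissuePhysiology,
                     blood_signal, characteristic_frequency, oef_from_r2p,
                     tissue_signal_asymptotic_r2p)
from .simulate import ASESignal

__all__ = ["fit_loglinear", "fit_nonlinear_ls", "long_tau_threshold",
           "LSFitResult", "forward_model_1c", "forward_model_2c"]

#: reference physiology at which the default long-tau threshold is computed
_REFERENCE_OEF = 0.40


@dataclass
class LSFitResult:
    r2p: float
    dbv: float
    oef: float
    s0: float | None = None
    n_points: int | None = None
    residual_norm: float | None = None
    converged: bool = True
    status: str = "ok"

    def as_dict(self) -> dict:
        return {"r2p": self.r2p, "dbv": self.dbv, "oef": self.oef,
                "s0": self.s0, "converged": self.converged,
                "status": self.status}


def long_tau_threshold(proto: AcquisitionProtocol,
                       kappa: float = KAPPA_DEFAULT,
                       hct: float = 0.40,
                       oef: float = _REFERENCE_OEF) -> float:
    """Smallest scheduled tau strictly above tc at reference physiology.

    With the default schedule, kappa = 1.76 and OEF = 40% this is 16 ms
    (tc ~ 12.4 ms), so the log-linear fit uses 13 long-tau points plus the
    spin echo, 14 data points in total.
    """
    phys = TissuePhysiology(oef=oef, hct=hct)
    tc = kappa / characteristic_frequency(phys, proto)
    tau = proto.tau
    above = tau[tau > tc]
    if above.size == 0:
        raise ValueError("no scheduled tau exceeds the transition time")
    return float(above.min())


def fit_loglinear(signal: ASESignal, proto: AcquisitionProtocol | None = None,
                  tau_threshold: float | None = None,
                  hct: float = 0.40,
                  kappa: float = KAPPA_DEFAULT) -> LSFitResult:
    """Log-linear (L-model) fit.

    OLS of ln S(tau) against tau over the points with tau >= threshold gives
    slope -R2' and an intercept whose excess over ln(SSEt) is DBV; OEF then
    follows from R2' and DBV.  R2' is invariant to rescaling the whole
    signal (the scale enters the intercept and ln SSEt equally).

    Voxels with non-positive amplitudes among the selected points are
    flagged and returned as missing values.
    """
    proto = proto or AcquisitionProtocol(tau_schedule=tuple(signal.tau))
    if tau_threshold is None:
        tau_threshold = long_tau_threshold(proto, kappa=kappa, hct=hct)
    tau = signal.tau
    amp = signal.amplitude
    sel = tau >= tau_threshold - 1e-12
    if sel.sum() < 2:
        raise ValueError("need at least two long-tau points")
    sse_t = signal.spin_echo_amplitude
    n_points = int(sel.sum()) + 1  # long-tau points plus the spin echo
    if sse_t <= 0 or np.any(amp[sel] <= 0):
        return LSFitResult(r2p=np.nan, dbv=np.nan, oef=np.nan,
                           n_points=n_points, converged=False,
                           status="non-positive amplitude")
    slope, intercept = np.polyfit(tau[sel], np.log(amp[sel]), 1)
    r2p = -float(slope)
    dbv = float(intercept - np.log(sse_t))
    oef = oef_from_r2p(r2p, dbv, hct, proto) if dbv > 0 else np.nan
    return LSFitResult(r2p=r2p, dbv=dbv, oef=oef, n_points=n_points)


# ----------------------------------------------------------------------------
# non-linear least squares
# ----------------------------------------------------------------------------

def forward_model_1c(theta, tau, proto: AcquisitionProtocol,
                     parameterisation: str = "R2p", r2t: float = 11.5,
                     hct: float = 0.40, kappa: float = KAPPA_DEFAULT):
    """One-compartment asymptotic model prediction for theta.

    ``theta`` is (R2', DBV, S0) or (OEF, DBV, S0) depending on the
    parameterisation.  DBV is clamped to (0, 1] so the model stays defined
    while an optimiser explores.
    """
    p1, dbv, s0 = theta
    dbv = min(max(float(dbv), 1e-6), 1.0)
    if parameterisation == "R2p":
        r2p = max(float(p1), 0.0)
    elif parameterisation == "OEF":
        phys = TissuePhysiology(oef=min(max(float(p1), 0.0), 1.0), hct=hct)
        r2p = dbv * characteristic_frequency(phys, proto)
    else:
        raise ValueError("parameterisation must be 'R2p' or 'OEF'")
    return tissue_signal_asymptotic_r2p(r2p, dbv, s0, r2t, proto, tau, kappa)


def forward_model_2c(theta, tau, proto: AcquisitionProtocol,
                     blood: BloodCompartment | None = None,
                     parameterisation: str = "R2p", r2t: float = 11.5,
                     hct: float = 0.40, kappa: float = KAPPA_DEFAULT,
                     blood_model: str = "mn"):
    """Two-compartment asymptotic model prediction for theta.

    The tissue part is the asymptotic model; the blood compartment is
    weighted by the apparent blood volume zeta' = mb*nb*DBV.  In the R2'
    parameterisation the blood model's OEF is recovered from (R2', DBV).
    """
    blood = blood or BloodCompartment()
    p1, dbv, s0 = theta
    dbv = min(max(float(dbv), 1e-6), 1.0)
    if parameterisation == "R2p":
        r2p = max(float(p1), 0.0)
        oef = oef_from_r2p(r2p, dbv, hct, proto)
        oef = min(max(float(oef), 0.0), 1.0)
    else:
        oef = min(max(float(p1), 0.0), 1.0)
        r2p = dbv * characteristic_frequency(
            TissuePhysiology(oef=oef, hct=hct), proto)
    st = tissue_signal_asymptotic_r2p(r2p, dbv, 1.0, r2t, proto, tau, kappa)
    sb = blood_signal(oef, hct, blood, proto, tau, blood_model)
    zeta = blood.zeta(dbv, proto)
    return s0 * (zeta * sb + (1.0 - zeta) * st)


def fit_nonlinear_ls(signal: ASESignal,
                     model: str = "1c",
                     parameterisation: str = "R2p",
                     proto: AcquisitionProtocol | None = None,
                     blood: BloodCompartment | None = None,
                     init=None, hct: float = 0.40, r2t: float = 11.5,
                     kappa: float = KAPPA_DEFAULT,
                     blood_model: str = "mn") -> LSFitResult:
    """Bounded non-linear least squares over the full tau schedule.

    R2' is bounded to [0, 50] s^-1 (OEF to [0, 1]), DBV to [0, 1] and S0 is
    free but positive.  ``init`` overrides the default initialisation from
    the log-linear estimates.  Deterministic given the initialisation.
    """
    if model not in ("1c", "2c"):
        raise ValueError("model must be '1c' or '2c'")
    proto = proto or AcquisitionProtocol(tau_schedule=tuple(signal.tau))
    tau = signal.tau
    y = signal.amplitude

    if init is None:
        try:
            ll = fit_loglinear(signal, proto, hct=hct, kappa=kappa)
        except ValueError:
            ll = LSFitResult(r2p=np.nan, dbv=np.nan, oef=np.nan)
        r2p0 = ll.r2p if np.isfinite(ll.r2p) and ll.r2p > 0 else 3.0
        dbv0 = ll.dbv if np.isfinite(ll.dbv) and 0 < ll.dbv < 0.5 else 0.03
        s0_0 = signal.spin_echo_amplitude / np.exp(-r2t * proto.te)
        if parameterisation == "OEF":
            oef0 = oef_from_r2p(r2p0, dbv0, hct, proto)
            p1_0 = min(max(oef0, 0.05), 0.95) if np.isfinite(oef0) else 0.4
        else:
            p1_0 = r2p0
        init = (p1_0, dbv0, max(s0_0, 1e-6))

    if model == "1c":
        def predict(theta):
            return forward_model_1c(theta, tau, proto, parameterisation,
                                    r2t, hct, kappa)
    else:
        def predict(theta):
            return forward_model_2c(theta, tau, proto, blood,
                                    parameterisation, r2t, hct, kappa,
                                    blood_model)

    hi1 = 50.0 if parameterisation == "R2p" else 1.0
    bounds = ([0.0, 0.0, 1e-9], [hi1, 1.0, np.inf])
    x0 = np.clip(np.asarray(init, dtype=float),
                 np.asarray(bounds[0]) + 1e-9, np.asarray(bounds[1]))
    res = optimize.least_squares(lambda th: predict(th) - y, x0=x0,
                                 bounds=bounds, xtol=1e-14, ftol=1e-14,
                                 gtol=1e-14, max_nfev=2000)
    p1, dbv, s0 = res.x
    if parameterisation == "R2p":
        r2p, oef = p1, oef_from_r2p(p1, dbv, hct, proto)
    else:
        oef = p1
        r2p = dbv * characteristic_frequency(
            TissuePhysiology(oef=min(max(p1, 0.0), 1.0), hct=hct), proto)
    return LSFitResult(r2p=float(r2p), dbv=float(dbv), oef=float(oef),
                       s0=float(s0), residual_norm=float(np.linalg.norm(res.fun)),
                       converged=bool(res.success),
                       status=str(res.status) if res.success else res.message)
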