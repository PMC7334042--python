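"""Exhaustive grid-search Bayesian posterior over two qBOLD parameters.

The posterior of a parameter pair — (OEF, DBV) or (R2', DBV) — given an ASE
signal and the two-compartment model is sampled on a uniform grid: the
Gaussian log-likelihood -SSE/(2 sigma^2) is evaluated at every node,
combined with a flat prior over the grid box (optionally Gaussian priors),
and normalised stably in log space.  Marginalising the 2-D posterior along
either axis gives 1-D distributions whose means and standard deviations
quantify how separable the parameter pair is — the basis for preferring the
(R2', DBV) parameterisation in variational fitting.

S0 is held at its known simulation value during the search (the 2-D display
requires the remaining parameters fixed).

Both searches cover the same stated physiological region, OEF in [20, 70]%
and DBV in [0.3, 15]%: the (R2', DBV) search samples it uniformly in R2'
over the image of that box under R2' = dw(OEF)*DBV, with nodes whose
implied OEF falls outside the interval excluded.  The "OEF estimate"
derived from either posterior is summarised by first-order propagation of
the DBV-marginal uncertainty through OEF = 3 R2'/(4 pi gamma B0 dchi0 Hct
DBV), i.e. sd(OEF) = (mean OEF / mean DBV) * sd(DBV); a direct node-mapped
OEF distribution is also available but is heavy-tailed at low DBV.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .config import KAPPA_DEFAULT
from .models import (AcquisitionProtocol, BloodCompartment,
                     characteristic_frequency, oef_from_r2p,
                     TissuePhysiology)
from .infer_ls import forward_model_1c, forward_model_2c
from .simulate import ASESignal

__all__ = ["GridPosterior", "Marginal", "grid_posterior", "marginal",
           "default_axes", "derived_oef_distribution"]


@dataclass
class Marginal:
    """1-D marginal distribution on grid values."""

    name: str
    values: np.ndarray
    pmf: np.ndarray

    @property
    def mean(self) -> float:
        return float(np.sum(self.values * self.pmf))

    @property
    def sd(self) -> float:
        m = self.mean
        return float(np.sqrt(np.sum((self.values - m) ** 2 * self.pmf)))


@dataclass
class GridPosterior:
    """2-D grid posterior; axis1 indexes rows, axis2 columns."""

    axis1_name: str
    axis2_name: str
    axis1_values: np.ndarray
    axis2_values: np.ndarray
    log_posterior: np.ndarray  # unnormalised
    log_norm: float            # log of the normalisation constant

    @property
    def posterior(self) -> np.ndarray:
        """Normalised posterior mass per node (sums to 1)."""
        return np.exp(self.log_posterior - self.log_norm)

    @property
    def mode(self) -> tuple[float, float]:
        i, j = np.unravel_index(np.argmax(self.log_posterior),
                                self.log_posterior.shape)
        return float(self.axis1_values[i]), float(self.axis2_values[j])

    def to_frame(self) -> pd.DataFrame:
        rows = [(a1, a2, self.posterior[i, j])
                for i, a1 in enumerate(self.axis1_values)
                for j, a2 in enumerate(self.axis2_values)]
        return pd.DataFrame(rows, columns=[self.axis1_name, self.axis2_name,
                                           "posterior"])


def default_axes(axes: str, n1: int = 50, n2: int = 50,
                 proto: AcquisitionProtocol | None = None,
                 hct: float = 0.40):
    """Default uniform axis values for either parameterisation.

    OEF spans 20-70%, DBV 0.3-15%.  The R2' axis spans the full image of
    the OEF x DBV box under R2' = dw(OEF)*DBV, so the same parameter
    territory is searched in both parameterisations.
    """
    proto = proto or AcquisitionProtocol()
    dbv_vals = np.linspace(0.003, 0.15, n2)
    if axes == "OEF-DBV":
        return np.linspace(0.20, 0.70, n1), dbv_vals
    if axes == "R2p-DBV":
        dw_per_oef = characteristic_frequency(
            TissuePhysiology(oef=1.0, hct=hct), proto)
        r2p_lo = 0.20 * dw_per_oef * dbv_vals.min()
        r2p_hi = 0.70 * dw_per_oef * dbv_vals.max()
        return np.linspace(r2p_lo, r2p_hi, n1), dbv_vals
    raise ValueError("axes must be 'OEF-DBV' or 'R2p-DBV'")


def grid_predictions(axes: str, axis1_values, axis2_values, tau,
                     model: str = "2c", s0: float = 1.0,
                     proto: AcquisitionProtocol | None = None,
                     blood: BloodCompartment | None = None,
                     hct: float = 0.40, r2t: float = 11.5,
                     kappa: float = KAPPA_DEFAULT) -> np.ndarray:
    """Noise-free model predictions at every node, shape (n1, n2, n_tau).

    Precomputing this once lets many noise realisations of the same clean
    signal be scored cheaply.
    """
    proto = proto or AcquisitionProtocol(tau_schedule=tuple(tau))
    param = "OEF" if axes.startswith("OEF") else "R2p"
    axis1_values = np.asarray(axis1_values, dtype=float)
    axis2_values = np.asarray(axis2_values, dtype=float)
    tau = np.asarray(tau, dtype=float)
    pred = np.empty((axis1_values.size, axis2_values.size, tau.size))
    for i, p1 in enumerate(axis1_values):
        for j, dbv in enumerate(axis2_values):
            theta = (p1, dbv, s0)
            if model == "2c":
                pred[i, j] = forward_model_2c(theta, tau, proto, blood,
                                              param, r2t, hct, kappa)
            elif model == "1c":
                pred[i, j] = forward_model_1c(theta, tau, proto, param, r2t,
                                              hct, kappa)
            else:
                raise ValueError("model must be '1c' or '2c'")
    return pred


def oef_box_mask(axis1_values, axis2_values, hct: float = 0.40,
                 proto: AcquisitionProtocol | None = None,
                 oef_interval: tuple[float, float] = (0.20, 0.70)):
    """Mask of (R2', DBV) nodes whose implied OEF lies in the search box."""
    proto = proto or AcquisitionProtocol()
    oef_nodes = oef_from_r2p(np.asarray(axis1_values)[:, None],
                             np.asarray(axis2_values)[None, :], hct, proto)
    return (oef_nodes >= oef_interval[0]) & (oef_nodes <= oef_interval[1])


def grid_posterior(signal: ASESignal, noise_sd: float,
                   axes: str = "R2p-DBV",
                   axis1_values=None, axis2_values=None,
                   model: str = "2c", s0: float = 1.0,
                   proto: AcquisitionProtocol | None = None,
                   blood: BloodCompartment | None = None,
                   hct: float = 0.40, r2t: float = 11.5,
                   kappa: float = KAPPA_DEFAULT,
                   priors=None, predictions: np.ndarray | None = None,
                   restrict_to_oef_box: bool = True) -> GridPosterior:
    """Evaluate the posterior at every node of a uniform parameter grid.

    ``noise_sd`` is the known Gaussian noise SD (from the simulated SNR).
    ``priors``, when given, is a pair of (mean, sd) tuples for axis1/axis2
    Gaussian priors; the default is a flat prior over the grid box, under
    which node ordering by posterior equals ordering by -SSE.  For
    ``axes="R2p-DBV"`` with ``restrict_to_oef_box`` the flat prior covers
    only nodes whose implied OEF lies within the searched OEF interval, so
    both parameterisations explore the same physiological region.
    ``predictions`` may carry the output of :func:`grid_predictions` to
    avoid recomputation.
    """
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    proto = proto or AcquisitionProtocol(tau_schedule=tuple(signal.tau))
    if axis1_values is None or axis2_values is None:
        a1_def, a2_def = default_axes(axes, proto=proto, hct=hct)
        axis1_values = a1_def if axis1_values is None else axis1_values
        axis2_values = a2_def if axis2_values is None else axis2_values
    axis1_values = np.asarray(axis1_values, dtype=float)
    axis2_values = np.asarray(axis2_values, dtype=float)
    param = "OEF" if axes.startswith("OEF") else "R2p"
    y = signal.amplitude
    if predictions is None:
        predictions = grid_predictions(axes, axis1_values, axis2_values,
                                       signal.tau, model, s0, proto, blood,
                                       hct, r2t, kappa)
    sse = np.sum((y[None, None, :] - predictions) ** 2, axis=-1)
    log_post = -sse / (2.0 * noise_sd ** 2)
    if priors is not None:
        (m1, s1), (m2, s2) = priors
        log_post += (-0.5 * ((axis1_values[:, None] - m1) / s1) ** 2
                     - 0.5 * ((axis2_values[None, :] - m2) / s2) ** 2)
    if param == "R2p" and restrict_to_oef_box:
        mask = oef_box_mask(axis1_values, axis2_values, hct, proto)
        log_post = np.where(mask, log_post, -np.inf)
    names = ("OEF", "DBV") if param == "OEF" else ("R2p", "DBV")
    return GridPosterior(axis1_name=names[0], axis2_name=names[1],
                         axis1_values=axis1_values,
                         axis2_values=axis2_values,
                         log_posterior=log_post,
                         log_norm=float(logsumexp(log_post)))


def marginal(posterior: GridPosterior, axis: str) -> Marginal:
    """Marginalise the 2-D posterior onto one axis (row/column sums)."""
    p = posterior.posterior
    if axis == posterior.axis1_name:
        return Marginal(axis, posterior.axis1_values, p.sum(axis=1))
    if axis == posterior.axis2_name:
        return Marginal(axis, posterior.axis2_values, p.sum(axis=0))
    raise ValueError(f"axis must be {posterior.axis1_name!r} or "
                     f"{posterior.axis2_name!r}")


def derived_oef_distribution(posterior: GridPosterior,
                             hct: float = 0.40,
                             proto: AcquisitionProtocol | None = None):
    """Posterior-weighted node-mapped OEF distribution.

    For an (OEF, DBV) posterior this is the OEF marginal; for an
    (R2', DBV) posterior each grid node is mapped to OEF = 3 R2' /
    (4 pi gamma B0 dchi0 Hct DBV) and the node masses carried over.
    Returns (oef_values, weights, mean, sd).  Note the ratio makes this
    distribution heavy-tailed when low-DBV nodes carry mass; for a summary
    statistic prefer :func:`derived_oef_summary`.
    """
    proto = proto or AcquisitionProtocol()
    p = posterior.posterior
    if posterior.axis1_name == "OEF":
        marg = marginal(posterior, "OEF")
        return marg.values, marg.pmf, marg.mean, marg.sd
    oef_nodes = oef_from_r2p(posterior.axis1_values[:, None],
                             posterior.axis2_values[None, :], hct, proto)
    w = p.ravel()
    vals = np.asarray(oef_nodes).ravel()
    mean = float(np.sum(vals * w))
    sd = float(np.sqrt(np.sum((vals - mean) ** 2 * w)))
    return vals, w, mean, sd


def derived_oef_summary(posterior: GridPosterior, hct: float = 0.40,
                        proto: AcquisitionProtocol | None = None):
    """(mean, sd) of the OEF estimate derived from a grid posterior.

    The posterior-mean OEF is the OEF marginal mean (OEF axes) or the
    node-mapped posterior mean (R2' axes).  Its uncertainty is obtained by
    first-order propagation of the DBV-marginal SD through the inverse
    relation OEF = 3 R2' / (4 pi gamma B0 dchi0 Hct DBV), whose dominant
    sensitivity is dOEF/dDBV = -OEF/DBV:

        sd(OEF) = (mean OEF / mean DBV) * sd(DBV).
    """
    proto = proto or AcquisitionProtocol()
    dbv_marg = marginal(posterior, "DBV")
    if posterior.axis1_name == "OEF":
        oef_mean = marginal(posterior, "OEF").mean
    else:
        oef_nodes = oef_from_r2p(posterior.axis1_values[:, None],
                                 posterior.axis2_values[None, :], hct, proto)
        oef_mean = float(np.sum(np.asarray(oef_nodes) * posterior.posterior))
    sd = (oef_mean / dbv_marg.mean) * dbv_marg.sd
    return float(oef_mean), float(sd)
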