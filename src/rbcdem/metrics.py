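"""Macroscopic observables of RBC-laden channel flow.

The two headline quantities of the Fahraeus-Lindqvist validation are measured
from volumetric fluxes through a fixed cross-section plane:

* discharge hematocrit ``Ht_d = <Q_RBCs> / <Q_blood>`` — exceeds the channel
  hematocrit when cells concentrate in the fast channel core,
* relative apparent viscosity ``mu_rel = Q_plasma,theory / <Q_blood>`` — the
  theoretical pure-plasma (Hagen-Poiseuille) flux at the same driving divided
  by the simulated suspension flux.

Both are compared against the empirical correlations of Pries and co-workers
for microvessels (diameter D in micrometers), and the agreement is quantified
by the percentage error ``100 |x_sim - x_Pries| / x_Pries``.

The hematocrit skewness index ``S_H = | int_0^1/2 Ht dw / int Ht dw - 1/2 |``
quantifies profile asymmetry along a measurement cut (w the normalized cut
coordinate), and deformation-index population statistics summarize how hard
the cells are being worked by the local flow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PriesReference",
    "SteadinessDetector",
    "discharge_hematocrit",
    "relative_viscosity",
    "pries_reference",
    "percentage_error",
    "skewness_index",
    "di_statistics",
]


@dataclass(frozen=True)
class PriesReference:
    """Empirical microvessel reference values at (D [um], Ht_c)."""

    D: float
    Ht_c: float
    X: float
    Ht_d_ref: float
    mu_rel_045: float
    C: float
    mu_rel_ref: float


def pries_reference(D_um: float, Ht_c: float) -> PriesReference:
    """Evaluate the Pries discharge-hematocrit and viscosity correlations.

    ``D_um`` is the channel diameter in micrometers (the convention the
    correlations were fitted in); ``Ht_c`` the channel (tube) hematocrit.
    """
    D = float(D_um)
    if not (0.0 <= Ht_c <= 0.6):
        raise ValueError("Ht_c out of the correlation range [0, 0.6]")
    X = 1.0 + 1.7 * np.exp(-0.35 * D) - 0.6 * np.exp(-0.01 * D)
    if abs(1.0 - X) < 1e-10:  # wide-tube limit: Ht_d -> Ht_c / X
        Ht_d = Ht_c / X
    else:
        A = X / (2.0 - 2.0 * X)
        Ht_d = -A + np.sqrt(A * A + Ht_c / (1.0 - X))
    mu45 = 3.2 + 220.0 * np.exp(-1.3 * D) - 2.44 * np.exp(-0.06 * D**0.645)
    gate = 1.0 / (1.0 + 1e-11 * D**12)
    C = (0.8 + np.exp(-0.075 * D)) * (-1.0 + gate) + gate
    mu_rel = 1.0 + (mu45 - 1.0) * ((1.0 - Ht_d) ** C - 1.0) / ((1.0 - 0.45) ** C - 1.0)
    return PriesReference(D=D, Ht_c=Ht_c, X=float(X), Ht_d_ref=float(Ht_d),
                          mu_rel_045=float(mu45), C=float(C), mu_rel_ref=float(mu_rel))


def percentage_error(x_sim: float, x_pries: float) -> float:
    """``100 |x_sim - x_Pries| / x_Pries`` [%]."""
    if x_pries == 0:
        raise ValueError("reference value is zero; percentage error undefined")
    return 100.0 * abs(x_sim - x_pries) / abs(x_pries)


class SteadinessDetector:
    """Declares a flux record steady when Ht_d and mu_rel drift by less than
    ``tol`` (relative) between two consecutive windows of duration ``window``.
    """

    def __init__(self, window: float, plasma_flux: float, tol: float = 0.01):
        if window <= 0 or plasma_flux <= 0:
            raise ValueError("window and plasma_flux must be positive")
        self.window = window
        self.plasma_flux = plasma_flux
        self.tol = tol

    def _window_values(self, samples: pd.DataFrame):
        t = samples["t"].to_numpy()
        t_end = t[-1]
        vals = []
        for k in (2, 1):  # second-to-last, last window
            lo, hi = t_end - k * self.window, t_end - (k - 1) * self.window
            m = (t > lo) & (t <= hi)
            if not np.any(m) or t[m][0] - lo > 0.5 * self.window:
                return None
            qb = samples.loc[m, "Q_blood"].mean()
            qr = samples.loc[m, "Q_RBCs"].mean()
            vals.append((qr / qb, self.plasma_flux / qb))
        return vals

    def is_steady(self, samples: pd.DataFrame) -> bool:
        if len(samples) < 4 or samples["t"].iloc[-1] - samples["t"].iloc[0] < 2 * self.window:
            return False
        vals = self._window_values(samples)
        if vals is None:
            return False
        (h2, m2), (h1, m1) = vals
        dh = abs(h1 - h2) / max(abs(h2), 1e-12)
        dm = abs(m1 - m2) / max(abs(m2), 1e-12)
        return dh < self.tol and dm < self.tol

    def steady_slice(self, samples: pd.DataFrame) -> pd.DataFrame:
        """The last two windows (the averaging region for final metrics)."""
        t = samples["t"].to_numpy()
        return samples[t > t[-1] - 2 * self.window]


def discharge_hematocrit(samples: pd.DataFrame, detector: SteadinessDetector | None = None) -> float:
    """Time-mean RBC flux over time-mean suspension flux.

    With a detector attached, the record must satisfy the steadiness criterion
    and the mean is taken over the last two windows.
    """
    if detector is not None:
        if not detector.is_steady(samples):
            raise RuntimeError("flux record has not reached steady state")
        samples = detector.steady_slice(samples)
    qb = samples["Q_blood"].mean()
    if qb <= 0:
        raise ValueError("mean Q_blood must be positive")
    return float(samples["Q_RBCs"].mean() / qb)


def relative_viscosity(samples: pd.DataFrame, plasma_flux: float,
                       detector: SteadinessDetector | None = None) -> float:
    """Theoretical pure-plasma flux divided by the time-mean suspension flux."""
    if detector is not None:
        if not detector.is_steady(samples):
            raise RuntimeError("flux record has not reached steady state")
        samples = detector.steady_slice(samples)
    qb = samples["Q_blood"].mean()
    if qb <= 0:
        raise ValueError("mean Q_blood must be positive")
    return float(plasma_flux / qb)


def skewness_index(w: np.ndarray, ht: np.ndarray) -> float:
    """Hematocrit skewness ``S_H`` of a profile sampled on w in [-1/2, 1/2].

    Trapezoidal quadrature of ``| int_0^1/2 Ht dw / int_-1/2^1/2 Ht dw - 1/2 |``.
    """
    w = np.asarray(w, dtype=float)
    ht = np.asarray(ht, dtype=float)
    if w.ndim != 1 or w.shape != ht.shape or len(w) < 3:
        raise ValueError("need matching 1-D arrays of at least 3 samples")
    if np.any(np.diff(w) <= 0):
        raise ValueError("w must be strictly increasing")
    if w[0] > -0.5 + 1e-9 or w[-1] < 0.5 - 1e-9:
        raise ValueError("w must cover [-0.5, 0.5]")
    if np.any(ht < 0):
        raise ValueError("hematocrit samples must be nonnegative")
    total = np.trapezoid(ht, w)
    if total <= 0:
        raise ValueError("profile integrates to zero; skewness undefined")
    # resample to place a node exactly at w = 0 for the half-range integral
    w_half = np.linspace(0.0, 0.5, 1 + 8 * len(w))
    upper = np.trapezoid(np.interp(w_half, w, ht), w_half)
    return float(abs(upper / total - 0.5))


def di_statistics(particles, n_bins: int = 20, n_stream_bins: int = 10, L: float | None = None):
    """Population statistics of the deformation index.

    Returns a dict with the population ``mean``, a fixed-bin ``hist`` (counts)
    with ``bin_edges`` on [0, 1), and, when the streamwise extent ``L`` is
    given, the spatially averaged ``<DI>`` per streamwise bin (NaN for empty
    bins) with the bin centres.
    """
    di = np.asarray(particles.DI, dtype=float)
    if di.size == 0:
        raise ValueError("empty particle population")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    hist, _ = np.histogram(di, bins=edges)
    out = {"mean": float(di.mean()), "hist": hist, "bin_edges": edges}
    if L is not None:
        z = np.mod(particles.pos[:, 2], L)
        zedges = np.linspace(0.0, L, n_stream_bins + 1)
        idx = np.clip(np.digitize(z, zedges) - 1, 0, n_stream_bins - 1)
        prof = np.full(n_stream_bins, np.nan)
        for b in range(n_stream_bins):
            m = idx == b
            if np.any(m):
                prof[b] = di[m].mean()
        out["stream_bin_centers"] = 0.5 * (zedges[:-1] + zedges[1:])
        out["stream_profile"] = prof
    return out
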