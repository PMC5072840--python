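"""Protein proxy: first-order linear filtering of a TF's mRNA time series.

Active-protein dynamics are coarse-grained to dp/dt = nu*m - lam*p.  Because
the regulation functions downstream respond only to ratios p/K with K fitted
on an arbitrary scale, the translation-to-degradation ratio nu/lam is fixed
to one, leaving dp/dt = lam*(m - p) with the single timescale
tau_1/2 = ln(2)/lam.  That timescale subsumes degradation, dilution, nuclear
transport and activation delays.

The filter is evaluated exactly on the cubic-spline interpolant of the mRNA
data: on each spline segment the convolution integral of exp(lam*t) against
a cubic polynomial is computed in closed form, so the only approximation is
the spline itself.  Initial conditions come from a warm-up: the measured
series is extended backward periodically by whole copies and the filter is
integrated from far enough back that the start transient has decayed below
``decay_tol``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import lfilter

from .dataio import GeneTimeSeries, Kind

__all__ = ["ProteinModel", "Propagator", "propagate", "half_life", "LAM_MIN", "LAM_MAX"]

# Half-lives from 1 to 120 min bracket the biologically inferred 5-50 min range.
LAM_MIN = math.log(2) / 120.0
LAM_MAX = math.log(2) / 1.0

DECAY_TOL = 1e-6  # warm-up transient must decay below this factor


@dataclass(frozen=True)
class ProteinModel:
    """One-parameter protein model; nu/lam is fixed at 1 by convention."""

    lam: float  # effective degradation rate, 1/min
    nu_over_lam: float = 1.0

    def __post_init__(self):
        if not (self.lam > 0):
            raise ValueError(f"lam must be positive, got {self.lam}")
        if self.nu_over_lam != 1.0:
            raise ValueError("nu/lam is fixed to 1 in this model")


def half_life(model: ProteinModel | float) -> float:
    """Effective protein half-life ln(2)/lam, minutes."""
    lam = model.lam if isinstance(model, ProteinModel) else float(model)
    if not lam > 0:
        raise ValueError("lam must be positive")
    return math.log(2) / lam


def _exp_moments(lam: float, h: float) -> np.ndarray:
    """I_k = int_0^h exp(-lam*(h-s)) s^k ds for k = 0..3 (closed form)."""
    out = np.empty(4)
    out[0] = -math.expm1(-lam * h) / lam
    for k in range(1, 4):
        out[k] = (h**k - k * out[k - 1]) / lam
    return out


class Propagator:
    """Reusable filter for one mRNA series; amortizes the spline construction.

    The periodic backward extension is built once for the smallest rate the
    caller will use (``lam_min``); calls with larger rates start the
    integration later inside the same extension.
    """

    def __init__(self, mrna: GeneTimeSeries, lam_min: float = LAM_MIN,
                 decay_tol: float = DECAY_TOL):
        if mrna.kind != Kind.mrna_level:
            raise ValueError(f"expected an mrna_level series, got {mrna.kind.value}")
        t = mrna.grid.times
        if t.size < 4:
            raise ValueError("cubic-spline propagation needs at least 4 grid points")
        self.series = mrna
        self._t = t
        self._span = mrna.grid.span
        self._decay_tol = decay_tol
        self._nseg_orig = t.size - 1
        self.max_copies = max(1, math.ceil(-math.log(decay_tol) / (lam_min * self._span)))
        # tile backward: each earlier copy contributes knots t[0..N-2]
        tiles_t = [t[:-1] + (k - self.max_copies) * self._span
                   for k in range(self.max_copies)]
        tiles_v = [mrna.values[:-1]] * self.max_copies
        self._ext_t = np.concatenate(tiles_t + [t])
        self._ext_v = np.concatenate(tiles_v + [mrna.values])
        spline = CubicSpline(self._ext_t, self._ext_v, bc_type="not-a-knot")
        self._coef = spline.c  # (4, nseg): c[0]*s^3 + ... + c[3]
        self._h = np.diff(self._ext_t)
        self._uniform = np.allclose(self._h, self._h[0], rtol=1e-12, atol=0.0)
        self.spline = spline

    def n_copies(self, lam: float) -> int:
        need = math.ceil(-math.log(self._decay_tol) / (lam * self._span))
        return int(min(max(need, 1), self.max_copies))

    def values(self, lam: float) -> np.ndarray:
        """Protein proxy at the original grid points for degradation rate lam."""
        if not lam > 0:
            raise ValueError("lam must be positive")
        start = (self.max_copies - self.n_copies(lam)) * self._nseg_orig
        h = self._h[start:]
        c = self._coef[:, start:]
        if self._uniform:
            I = _exp_moments(lam, float(h[0]))
            drive = lam * (c[3] * I[0] + c[2] * I[1] + c[1] * I[2] + c[0] * I[3])
            decay = math.exp(-lam * float(h[0]))
            # p[j+1] = decay * p[j] + drive[j]; run the scan in C via lfilter
            x = np.concatenate(([self._ext_v[start]], drive))
            p = lfilter([1.0], [1.0, -decay], x)
        else:
            p = np.empty(h.size + 1)
            p[0] = self._ext_v[start]
            for j in range(h.size):
                I = _exp_moments(lam, float(h[j]))
                drive = lam * (c[3, j] * I[0] + c[2, j] * I[1]
                               + c[1, j] * I[2] + c[0, j] * I[3])
                p[j + 1] = math.exp(-lam * float(h[j])) * p[j] + drive
        return p[-self._t.size:]

    def __call__(self, lam: float) -> GeneTimeSeries:
        return GeneTimeSeries(self.series.gene, Kind.protein_proxy,
                              self.values(lam), self.series.grid,
                              self.series.replicate)


def propagate(mrna: GeneTimeSeries, model: ProteinModel) -> GeneTimeSeries:
    """Filter an mRNA series into its protein proxy (kind = protein_proxy)."""
    return Propagator(mrna, lam_min=model.lam)(model.lam)
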