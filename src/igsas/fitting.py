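"""Experimental-curve preprocessing and R-factor screening of model libraries.

The goodness-of-fit statistic is the crystallography-style R-factor

    R = sum |I_expt(Q_i) - eta I_model(Q_i)| / sum |I_expt(Q_i)| x 100,

with the scale factor eta minimizing the L1 discrepancy.  Neutron model
curves receive a flat incoherent-background addition of 2.0% of the
experimental I(0) before comparison.  Screening ranks every library model
by R-factor and keeps the best n (default 100).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .mc import ModelLibrary
from .scattering import GUINIER_WINDOW, ScatteringCurve, debye_curve, guinier_fit

#: Q-grid sizes used for the two modalities on [0, 1.5] nm^-1
N_POINTS_XRAY = 825
N_POINTS_NEUTRON = 146
QMAX_DEFAULT = 1.5
SANS_BACKGROUND_FRACTION = 0.02

#: histogram bin for fast model curves during screening (nm)
SCREEN_BIN_WIDTH = 0.02


@dataclass
class FitRecord:
    model_id: int
    eta: float
    rfactor: float            # percent
    background: float = 0.0
    curve_label: str = ""


@dataclass
class ScreenResult:
    """Ranked fit records plus the selected best-fit set."""

    records: pd.DataFrame     # model_id, rg, eta, rfactor, selected
    top_ids: np.ndarray
    rg_expt: float
    rg_band: tuple            # (0.98, 1.02) x experimental R_G
    curve_label: str = ""

    @property
    def best(self) -> pd.Series:
        return self.records.iloc[0]


def preprocess_curve(curve: ScatteringCurve, n_points: int,
                     qmax: float = QMAX_DEFAULT,
                     guinier_window: tuple = GUINIER_WINDOW) -> ScatteringCurve:
    """Uniform Q grid on [0, qmax] extended to zero Q.

    Interior points come from monotone piecewise-cubic interpolation of the
    measured curve; points below the first measured Q follow the Guinier
    model fitted in the low-Q window, rescaled to join the measured curve
    continuously at its first point.
    """
    if len(curve) == 0:
        raise ValueError("empty curve")
    if qmax > curve.q[-1] + 1e-12:
        raise ValueError("qmax beyond the measured Q range")
    qgrid = np.linspace(0.0, qmax, n_points)
    interp = PchipInterpolator(curve.q, curve.i, extrapolate=False)
    i_out = np.empty(n_points)
    q0 = curve.q[0]
    inside = qgrid >= q0 - 1e-12
    i_out[inside] = interp(np.clip(qgrid[inside], q0, curve.q[-1]))
    if not np.all(inside):
        lo, hi = guinier_window
        win = (max(lo, q0), hi)
        gr = guinier_fit(curve, win)
        if not gr.valid:
            raise ValueError("low-Q window unusable for Guinier extrapolation")
        i_at_q0 = float(interp(q0))
        if i_at_q0 <= 0:
            raise ValueError("non-positive intensity at the first measured point")
        ext = qgrid[~inside]
        i_out[~inside] = i_at_q0 * np.exp(-(gr.rg ** 2) * (ext ** 2 - q0 ** 2) / 3.0)
    sigma = None
    if curve.sigma is not None:
        sigma = np.interp(qgrid, curve.q, curve.sigma,
                          left=curve.sigma[0], right=curve.sigma[-1])
    return ScatteringCurve(qgrid, i_out, sigma, curve.modality,
                           label=curve.label or "preprocessed")


def _golden_section(fun, lo: float, hi: float, rel_tol: float = 1e-6) -> float:
    """Golden-section minimum on [lo, hi]; plateau ties resolve to smaller x."""
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = fun(c), fun(d)
    while (b - a) > rel_tol * max(abs(a), abs(b), 1e-12):
        if fc <= fd:          # <= keeps the left (smaller-eta) side on ties
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = fun(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = fun(d)
    return a if fun(a) <= fun(b) else b


def rfactor(expt: ScatteringCurve, model: ScatteringCurve,
            eta_mode: str = "fit") -> tuple[float, float]:
    """R-factor (percent) and the L1-optimal scale factor eta.

    The two curves must share one Q grid; silent re-interpolation would
    hide grid mismatches, so it is an error instead.  ``eta_mode='fixed'``
    skips the search and uses eta = 1.
    """
    if len(expt) != len(model) or not np.allclose(expt.q, model.q, atol=1e-9):
        raise ValueError("experimental and model curves are on different Q grids")
    ie, im = expt.i, model.i
    denom = float(np.sum(np.abs(ie)))
    if denom == 0:
        raise ValueError("experimental curve is identically zero")
    if eta_mode == "fixed":
        eta = 1.0
    else:
        pos = im > 0
        if not np.any(pos):
            raise ValueError("model curve has no positive intensities")
        ratios = ie[pos] / im[pos]
        ratios = ratios[ratios > 0]
        if len(ratios) == 0:
            raise ValueError("cannot bracket eta: no positive intensity ratios")
        lo, hi = 0.5 * float(ratios.min()), 2.0 * float(ratios.max())

        def objective(eta_):
            return float(np.sum(np.abs(ie - eta_ * im)))

        eta = _golden_section(objective, lo, hi)
        # the L1 optimum sits at a kink (an intensity ratio): snap to the
        # best nearby kink, ties toward the smaller eta
        near = ratios[np.abs(ratios - eta) <= 1e-3 * abs(eta)]
        for cand in np.sort(near):
            if objective(float(cand)) <= objective(eta):
                eta = float(cand)
                break
    r = float(np.sum(np.abs(ie - eta * im)) / denom * 100.0)
    return r, float(eta)


def apply_sans_background(model_curve: ScatteringCurve,
                          i0_expt: float) -> ScatteringCurve:
    """Add the flat incoherent background, 2.0% of the experimental I(0)."""
    if model_curve.modality != "neutron":
        raise ValueError("flat incoherent background applies to neutron curves only")
    b = SANS_BACKGROUND_FRACTION * i0_expt
    return model_curve.with_intensity(model_curve.i + b)


def screen_library(library: ModelLibrary, expt: ScatteringCurve,
                   n_select: int = 100,
                   bin_width: float = SCREEN_BIN_WIDTH,
                   guinier_window: tuple = GUINIER_WINDOW) -> ScreenResult:
    """Rank every library model against an experimental curve by R-factor.

    Model curves are computed on the experimental Q grid (histogram-binned
    Debye sums); for neutron curves the flat background is added to the
    model side before the R-factor.  The result carries the (R_G,
    R-factor) table for plotting and the +-2% experimental R_G band.
    """
    if len(library) == 0:
        raise ValueError("empty model library")
    import warnings as _warnings
    if n_select > len(library):
        _warnings.warn(f"n_select={n_select} exceeds library size {len(library)}; "
                       "selecting all", RuntimeWarning, stacklevel=2)
        n_select = len(library)

    gr = guinier_fit(expt, guinier_window)
    i0_expt = expt.i0() if expt.q[0] == 0 else gr.i0

    # shared quadrature: one sinc matrix over a common pair-distance grid
    from scipy.spatial.distance import pdist
    from .scattering import _sinc
    # bounding-box diagonals bound every pair distance, so one grid serves all
    spans = library.coords.max(axis=1) - library.coords.min(axis=1)
    rmax = float(np.linalg.norm(spans, axis=1).max())
    edges = np.arange(0.0, rmax + 2 * bin_width, bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    smat = _sinc(np.outer(expt.q, centers))
    f = library.template.f
    uniform_f = bool(np.allclose(f, f[0]))
    self_term = float((f ** 2).sum())
    ff = float(f[0] * f[0]) if uniform_f else None

    rows = []
    background = SANS_BACKGROUND_FRACTION * i0_expt if expt.modality == "neutron" else 0.0
    for k in range(len(library)):
        if uniform_f:
            d = pdist(library.coords[k])
            hist, _ = np.histogram(d, bins=edges)
            hist = hist * ff
        else:
            m = library.model(k)
            mc = debye_curve(m, expt.q, bin_width=bin_width, modality=expt.modality)
            i_model = mc.i
            hist = None
        if hist is not None:
            i_model = self_term + 2.0 * (smat @ hist)
        mc = ScatteringCurve(expt.q, i_model + background, modality=expt.modality)
        r, eta = rfactor(expt, mc)
        rows.append((int(library.metadata["model_id"].iloc[k]),
                     float(library.rg[k]), eta, r))
    rec = pd.DataFrame(rows, columns=["model_id", "rg", "eta", "rfactor"])
    rec = rec.sort_values(["rfactor", "model_id"], kind="stable").reset_index(drop=True)
    rec["selected"] = np.arange(len(rec)) < n_select
    top = rec["model_id"].to_numpy()[:n_select]
    return ScreenResult(rec, top, gr.rg, (0.98 * gr.rg, 1.02 * gr.rg),
                        curve_label=expt.label)
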