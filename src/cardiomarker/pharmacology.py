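"""Cumulative concentration-effect datasets and Hill-model EC50 fitting.

The response model is the four-parameter Hill curve

    r(c) = floor + (ceiling - floor) * c^h / (c^h + EC50^h),

fitted by nonlinear least squares in log10-concentration space from a
deterministic multi-start grid (EC50 over the data's log range at 20
points, Hill coefficient over {0.5, 1, 2, 4} unless fixed).  EC50 is the
half-maximal-effect concentration (the standard Hill midpoint); the
alternative reading "concentration at which the response reaches a given
level" is available through :func:`concentration_at_response`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .errors import AnalysisError


@dataclass
class CEDataset:
    """Ascending concentrations with matched responses (cumulative protocol)."""

    concentrations_um: np.ndarray
    responses: np.ndarray
    n_per_point: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations_um, dtype=float)
        r = np.asarray(self.responses, dtype=float)
        n = np.asarray(self.n_per_point, dtype=int)
        if c.size != r.size or c.size != n.size:
            raise AnalysisError("concentrations, responses and n_per_point must match")
        if np.any(c <= 0):
            raise AnalysisError("concentrations must be positive")
        if c.size > 1 and not np.all(np.diff(c) > 0):
            raise AnalysisError("concentrations must be strictly ascending")
        self.concentrations_um, self.responses, self.n_per_point = c, r, n


@dataclass
class HillFit:
    floor: float
    ceiling: float
    ec50_um: float
    hill_coeff: float
    rss: float
    converged: bool


def hill_response(c, fit: HillFit):
    """Response of the fitted Hill curve at concentration(s) c (uM)."""
    c = np.asarray(c, dtype=float)
    occ = np.zeros_like(c)
    pos = c > 0
    ch = c[pos] ** fit.hill_coeff
    occ[pos] = ch / (ch + fit.ec50_um ** fit.hill_coeff)
    r = fit.floor + (fit.ceiling - fit.floor) * occ
    return r if r.shape else float(r)


def concentration_at_response(fit: HillFit, response: float) -> float:
    """Invert the fitted curve: concentration (uM) producing ``response``."""
    q = (response - fit.floor) / (fit.ceiling - fit.floor)
    if not (0 < q < 1):
        raise AnalysisError(
            f"response {response:g} outside the open interval "
            f"({fit.floor:g}, {fit.ceiling:g}) spanned by the fit"
        )
    return fit.ec50_um * (q / (1.0 - q)) ** (1.0 / fit.hill_coeff)


def _model(lc: np.ndarray, floor: float, ceiling: float, lec50: float, h: float) -> np.ndarray:
    # Hill curve in log10 concentration: logistic with slope h
    return floor + (ceiling - floor) / (1.0 + 10.0 ** (h * (lec50 - lc)))


def fit_hill(data: CEDataset, h_fixed: Optional[float] = None,
             floor_fixed: Optional[float] = None,
             variances: Optional[Sequence[float]] = None) -> HillFit:
    """Fit the Hill model to a concentration-effect dataset.

    Requires at least as many distinct concentrations as free parameters
    (4 by default; each of ``h_fixed``/``floor_fixed`` removes one) and
    non-degenerate responses.  ``floor_fixed`` anchors the zero-
    concentration response — natural when responses are percent changes
    relative to each cell's own vehicle baseline, which are 0 at c = 0 by
    construction.  Weights are uniform unless per-point ``variances`` are
    supplied (then 1/variance).  The best of the deterministic multi-start
    grid is returned; ``converged=False`` flags a fit that did not meet
    tolerance, with the best-found parameters.
    """
    c = data.concentrations_um
    r = data.responses
    n_free = 4 - (h_fixed is not None) - (floor_fixed is not None)
    if np.unique(c).size < n_free:
        raise AnalysisError(f"need >= {n_free} distinct concentrations")
    if float(np.std(r)) == 0.0:
        raise AnalysisError("degenerate data: responses have zero variance")
    lc = np.log10(c)
    if variances is not None:
        w = 1.0 / np.sqrt(np.asarray(variances, dtype=float))
    else:
        w = np.ones_like(r)

    lo, hi = float(lc.min()), float(lc.max())
    lec50_starts = np.linspace(lo, hi, 20)
    h_starts = [h_fixed] if h_fixed is not None else [0.5, 1.0, 2.0, 4.0]
    floor0, ceil0 = float(r.min()), float(r.max())

    # screen the deterministic start grid cheaply: at fixed (lec50, h) the
    # model is linear in (floor, ceiling), so profile them by weighted
    # linear least squares and rank the starts by the profiled rss
    screened: list[tuple[float, float, float, float, float]] = []
    for h0 in h_starts:
        for l0 in lec50_starts:
            occ = 1.0 / (1.0 + 10.0 ** (h0 * (l0 - lc)))
            if floor_fixed is None:
                design = np.column_stack([w * (1.0 - occ), w * occ])
                target = w * r
            else:
                design = (w * occ)[:, None]
                target = w * (r - floor_fixed * (1.0 - occ))
            coef, *_ = np.linalg.lstsq(design, target, rcond=None)
            rss0 = float(np.sum((design @ coef - target) ** 2))
            f0 = floor_fixed if floor_fixed is not None else float(coef[0])
            c0 = float(coef[-1])
            screened.append((rss0, f0, c0, l0, h0))
    screened.sort(key=lambda s: (s[0], s[3], s[4]))

    def unpack(p: np.ndarray) -> tuple[float, float, float, float]:
        i = 0
        if floor_fixed is None:
            fl = p[i]; i += 1
        else:
            fl = floor_fixed
        ce = p[i]; i += 1
        le = p[i]; i += 1
        hh = h_fixed if h_fixed is not None else p[i]
        return fl, ce, le, hh

    best = None
    for rss0, f0, c0, l0, h0 in screened[:3]:
        def resid(p):
            fl, ce, le, hh = unpack(p)
            return w * (_model(lc, fl, ce, le, hh) - r)
        x0, blo, bhi = [], [], []
        if floor_fixed is None:
            x0 += [f0]; blo += [-np.inf]; bhi += [np.inf]
        x0 += [c0, l0]; blo += [-np.inf, lo - 3.0]; bhi += [np.inf, hi + 3.0]
        if h_fixed is None:
            x0 += [h0]; blo += [0.05]; bhi += [20.0]
        try:
            sol = least_squares(resid, x0, bounds=(blo, bhi),
                                xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=2000)
        except Exception:
            continue
        rss = float(np.sum(sol.fun ** 2))
        if best is None or rss < best[0]:
            best = (rss, sol)
    if best is None:
        raise AnalysisError("Hill fit failed from every start")

    rss, sol = best
    fl, ce, le, hh = unpack(sol.x)
    converged = bool(sol.status > 0 and math.isfinite(rss))
    return HillFit(floor=float(fl), ceiling=float(ce), ec50_um=float(10.0 ** le),
                   hill_coeff=float(hh), rss=rss, converged=converged)


def build_ce_curve(summaries: Sequence[dict]) -> CEDataset:
    """Assemble a CE dataset from per-concentration condition summaries.

    Each summary must carry ``concentration_um`` and ``response`` (and may
    carry ``n``); duplicates of a concentration are averaged with their
    total n recorded.
    """
    rows = []
    for s in summaries:
        if "concentration_um" not in s or s["concentration_um"] is None:
            raise AnalysisError("summary missing concentration metadata")
        rows.append((float(s["concentration_um"]), float(s["response"]),
                     int(s.get("n", 1))))
    rows.sort()
    concs, resps, ns = [], [], []
    for c, r, n in rows:
        if concs and math.isclose(c, concs[-1], rel_tol=1e-12):
            total = ns[-1] + n
            resps[-1] = (resps[-1] * ns[-1] + r * n) / total
            ns[-1] = total
        else:
            concs.append(c)
            resps.append(r)
            ns.append(n)
    return CEDataset(np.asarray(concs), np.asarray(resps), np.asarray(ns))
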