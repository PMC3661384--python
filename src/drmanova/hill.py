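"""Four-parameter logistic ("hill") dose-response curve fitting.

Model (log10-dose 4PL)::

    y(dose) = Min + (Max - Min) / (1 + 10**(slope * (log10(dose) - log10(IC50))))

With ``slope > 0`` the curve decreases from Max at low dose to Min at high
dose; increasing curves are accommodated by a negative slope. Fits are
canonicalised so that ``Max >= Min`` (the (slope, Min, Max) sign/swap
ambiguity of the 4PL is resolved deterministically).

The fitter exploits the partially linear structure of the model: for fixed
(log10 IC50, slope) the asymptotes enter linearly and are profiled out in
closed form (variable projection). A deterministic multi-start grid over
(log10 IC50, slope) is followed by Levenberg-Marquardt refinement of the
two nonlinear parameters, vectorised across curves so that whole cohorts
(one curve per individual) are fitted in a handful of array operations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

LN10 = np.log(10.0)

# multi-start grid margins / convergence bounds (log10-dose units)
_GRID_MARGIN = 0.75
_BOUND_MARGIN = 2.0  # IC50 must stay inside [dose_min/100, dose_max*100]
_SLOPE_GRID = np.array([-3.0, -1.8, -1.0, -0.5, 0.5, 1.0, 1.8, 3.0])
_SLOPE_MAX = 50.0


@dataclass
class HillFit:
    """Result of a 4PL fit to one dose-response curve."""

    min_asymptote: float
    max_asymptote: float
    ic50: float
    slope: float
    converged: bool
    rss: float


def hill_curve(
    doses: np.ndarray,
    min_asymptote: float,
    max_asymptote: float,
    ic50: float,
    slope: float,
) -> np.ndarray:
    """Evaluate the 4PL model on a dose grid (doses must be positive)."""
    doses = np.asarray(doses, dtype=float)
    x = np.log10(doses)
    f = expit(-LN10 * slope * (x - np.log10(ic50)))
    return min_asymptote + (max_asymptote - min_asymptote) * f


def _profile_linear(x: np.ndarray, Y: np.ndarray, q: np.ndarray, s: np.ndarray):
    """Profile out the linear (offset, range) parameters per curve.

    Returns (a, b, f, resid, rss) where the fitted curve is ``a + b * f``.
    """
    d = x.size
    f = expit(-LN10 * s[:, None] * (x[None, :] - q[:, None]))
    Sf = f.sum(axis=1)
    Sff = (f * f).sum(axis=1)
    Sy = Y.sum(axis=1)
    Sfy = (f * Y).sum(axis=1)
    det = d * Sff - Sf * Sf
    ok = det > 1e-12 * d * np.maximum(Sff, 1e-300)
    b = np.where(ok, (d * Sfy - Sf * Sy) / np.where(ok, det, 1.0), 0.0)
    a = (Sy - b * Sf) / d
    resid = Y - a[:, None] - b[:, None] * f
    rss = (resid * resid).sum(axis=1)
    return a, b, f, resid, rss


def fit_hill_curves(doses: np.ndarray, Y: np.ndarray, max_iter: int = 60) -> list[HillFit]:
    """Fit one 4PL curve per row of ``Y`` over a shared dose grid.

    Deterministic: a fixed multi-start grid over (log10 IC50, slope) with
    closed-form asymptotes, then damped Gauss-Newton refinement. A fit is
    flagged ``converged=False`` when the responses are flat, the fitted
    range collapses, or the IC50 runs to the search bounds
    [dose_min/100, dose_max*100].
    """
    doses = np.asarray(doses, dtype=float)
    if np.any(doses <= 0):
        raise ValueError("doses must be strictly positive for a log10-dose fit")
    if doses.size < 4:
        raise ValueError("need at least 4 doses to fit 4 parameters")
    if np.any(np.diff(doses) <= 0):
        raise ValueError("doses must be strictly increasing")
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[1] != doses.size:
        raise ValueError("response matrix width must equal the dose grid length")
    n, d = Y.shape
    x = np.log10(doses)
    lo, hi = x[0] - _BOUND_MARGIN, x[-1] + _BOUND_MARGIN

    y_range = Y.max(axis=1) - Y.min(axis=1)
    y_scale = np.maximum(np.abs(Y).max(axis=1), 1.0)
    flat = y_range <= 1e-12 * y_scale

    # --- multi-start grid (design shared across curves per grid point) ---
    # closed-form 2-parameter least squares per grid point: with shared f,
    # rss = sum(y^2) - a*sum(y) - b*sum(f*y) at the normal-equation optimum
    q_grid = np.linspace(x[0] - _GRID_MARGIN, x[-1] + _GRID_MARGIN, 17)
    Sy = Y.sum(axis=1)
    Syy = (Y * Y).sum(axis=1)
    best_rss = np.full(n, np.inf)
    best_q = np.full(n, x.mean())
    best_s = np.ones(n)
    for qg in q_grid:
        for sg in _SLOPE_GRID:
            f = expit(-LN10 * sg * (x - qg))
            Sf = f.sum()
            Sff = float(f @ f)
            det = d * Sff - Sf * Sf
            if det <= 1e-12 * d * max(Sff, 1e-300):
                continue
            Sfy = Y @ f
            bg = (d * Sfy - Sf * Sy) / det
            ag = (Sy - bg * Sf) / d
            rss = Syy - ag * Sy - bg * Sfy
            better = rss < best_rss
            if better.any():
                best_rss[better] = rss[better]
                best_q[better] = qg
                best_s[better] = sg

    # --- Levenberg-Marquardt on (q, s) with profiled asymptotes ---
    # The active set is compacted every iteration: most curves converge in a
    # handful of steps and stragglers then iterate on small arrays.
    q = best_q.copy()
    s = best_s.copy()
    a, b, f, resid, rss = _profile_linear(x, Y, q, s)
    idx = np.flatnonzero(~flat)
    lam = np.full(idx.size, 1e-3)
    for _ in range(max_iter):
        if idx.size == 0:
            break
        Ya = Y[idx]
        qa, sa, ba = q[idx], s[idx], b[idx]
        fa, ra, rssa = f[idx], resid[idx], rss[idx]
        g = LN10 * fa * (1.0 - fa)  # d f / d(u) factor
        Jq = -ba[:, None] * sa[:, None] * g
        Js = ba[:, None] * (x[None, :] - qa[:, None]) * g
        # variable-projection (Kaufman) Jacobian: remove the span of the
        # linear design [1, f], else the GN Hessian ignores the linear
        # refit and steps collapse
        Sf = fa.sum(axis=1)
        Sff = (fa * fa).sum(axis=1)
        det_lin = d * Sff - Sf * Sf
        safe = np.where(np.abs(det_lin) > 1e-300, det_lin, 1.0)
        for v in (Jq, Js):
            Sv = v.sum(axis=1)
            Sfv = (fa * v).sum(axis=1)
            c0 = (Sff * Sv - Sf * Sfv) / safe
            c1 = (d * Sfv - Sf * Sv) / safe
            v -= c0[:, None] + c1[:, None] * fa
        A11 = (Jq * Jq).sum(axis=1)
        A12 = (Jq * Js).sum(axis=1)
        A22 = (Js * Js).sum(axis=1)
        g1 = -(Jq * ra).sum(axis=1)
        g2 = -(Js * ra).sum(axis=1)

        k = idx.size
        accepted = np.zeros(k, dtype=bool)
        done = np.zeros(k, dtype=bool)
        rem = np.arange(k)
        for _try in range(6):
            if rem.size == 0:
                break
            la = lam[rem]
            d11 = A11[rem] * (1.0 + la)
            d22 = A22[rem] * (1.0 + la)
            det = d11 * d22 - A12[rem] ** 2
            det = np.where(np.abs(det) > 1e-300, det, 1e-300)
            dq = (d22 * g1[rem] - A12[rem] * g2[rem]) / det
            ds = (d11 * g2[rem] - A12[rem] * g1[rem]) / det
            q_new = np.clip(qa[rem] + dq, lo, hi)
            s_new = np.clip(sa[rem] + ds, -_SLOPE_MAX, _SLOPE_MAX)
            a_n, b_n, f_n, r_n, rss_n = _profile_linear(x, Ya[rem], q_new, s_new)
            old = rssa[rem]
            improved = rss_n <= old + 1e-15
            if improved.any():
                hit = rem[improved]
                rows = idx[hit]
                q[rows] = q_new[improved]
                s[rows] = s_new[improved]
                a[rows] = a_n[improved]
                b[rows] = b_n[improved]
                f[rows] = f_n[improved]
                resid[rows] = r_n[improved]
                rss[rows] = rss_n[improved]
                moved = (np.abs(q_new - qa[rem]) + np.abs(s_new - sa[rem]))[improved]
                small = (old[improved] - rss_n[improved] <= 1e-8 * (old[improved] + 1e-30)) | (
                    moved < 1e-7
                )
                # curves pinned at the IC50 search bound are failures anyway
                pinned = (q_new[improved] <= lo + 1e-9) | (q_new[improved] >= hi - 1e-9)
                accepted[hit] = True
                done[hit] = small | pinned
                lam[hit] = np.maximum(lam[hit] / 3.0, 1e-12)
            rem = rem[~improved]
            lam[rem] *= 10.0
        done |= ~accepted  # no damped step helped: treat as converged
        keep = ~done
        idx = idx[keep]
        lam = lam[keep]

    # flat curves: offset-only fit
    if flat.any():
        a[flat] = Y[flat].mean(axis=1)
        b[flat] = 0.0
        rss[flat] = ((Y[flat] - a[flat, None]) ** 2).sum(axis=1)

    # canonicalise Max >= Min (flip slope sign / swap asymptotes)
    neg = b < 0
    a = np.where(neg, a + b, a)
    s = np.where(neg, -s, s)
    b = np.abs(b)

    # a parameter pinned at its search bound means the optimiser ran away
    # (IC50 outside [dose_min/100, dose_max*100] or a step-function slope)
    at_bound = (q <= lo + 1e-9) | (q >= hi - 1e-9) | (np.abs(s) >= _SLOPE_MAX - 1e-6)
    tiny_range = b <= 1e-8 * y_scale
    converged = ~(flat | at_bound | tiny_range) & np.isfinite(rss)

    return [
        HillFit(
            min_asymptote=float(a[i]),
            max_asymptote=float(a[i] + b[i]),
            ic50=float(10.0 ** q[i]),
            slope=float(s[i]),
            converged=bool(converged[i]),
            rss=float(rss[i]),
        )
        for i in range(n)
    ]


def fit_hill(doses: np.ndarray, responses: np.ndarray) -> HillFit:
    """Fit a single dose-response curve (see :func:`fit_hill_curves`)."""
    return fit_hill_curves(doses, np.asarray(responses, dtype=float)[None, :])[0]
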