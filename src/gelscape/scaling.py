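"""Critical-scaling fits for the percolation-like gelation transition.

The observables f_z (largest-cluster fraction) and ξ (correlation
length) diverge on approach to a critical mean coordination number z_c:

    f_z ~ (z_c − z)^(−σ),    ξ ~ (z_c − z)^(−ν),

and the saturation coordination number z_max(ε) approaches z_c as the
attraction strength ε approaches its critical value ε_c from below.
The fitters share one strategy: grid search over the unknown critical
value, ordinary least squares of log y on log(critical − x) at each
candidate, and selection of the candidate maximizing R², with
(block-)bootstrap standard errors.

The hyperscaling relation of percolation, τ = d/d_f + 1, links the
cluster-mass exponent τ to the fractal dimension d_f; with τ = 5/2 in
d = 3 it predicts d_f = 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DivergenceFit",
    "fit_divergence",
    "fit_zmax_vs_attraction",
    "hyperscaling_df",
]


@dataclass(frozen=True)
class DivergenceFit:
    critical_value: float       # z_c (or ε_c)
    exponent: float             # σ, ν, ... (positive for a divergence)
    amplitude: float
    r_squared: float
    window: tuple[float, float]
    critical_err: float = np.nan
    exponent_err: float = np.nan


def _loglog_fit(x, y, xc):
    lx = np.log(xc - x)
    ly = np.log(y)
    slope, intercept = np.polyfit(lx, ly, 1)
    resid = ly - (slope * lx + intercept)
    ss_tot = ((ly - ly.mean()) ** 2).sum()
    r2 = 1.0 - (resid**2).sum() / ss_tot if ss_tot > 0 else 0.0
    return -slope, np.exp(intercept), r2


def fit_divergence(x, y, candidates=None, n_boot: int = 200,
                   block: int = 10, seed: int | None = None) -> DivergenceFit:
    """Fit y ~ A (x_c − x)^(−exponent) with unknown critical point x_c.

    ``candidates``: grid of x_c values to search (default: 200 points
    from just above max(x) to max(x) + range(x)).  Bootstrap errors use
    contiguous blocks of ``block`` consecutive points to respect the
    temporal correlation of trajectory-derived series.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y) & (y > 0)
    x, y = x[ok], y[ok]
    if len(x) < 6:
        raise ValueError(f"need at least 6 usable points, got {len(x)}")
    if candidates is None:
        span = max(np.ptp(x), 1e-6)
        candidates = np.max(x) + np.linspace(1e-3 * span, span, 200)
    candidates = np.asarray(candidates, dtype=float)
    candidates = candidates[candidates > np.max(x)]
    if len(candidates) == 0:
        raise ValueError("all candidate critical values lie inside the data range")

    best = None
    for xc in candidates:
        expo, amp, r2 = _loglog_fit(x, y, xc)
        if best is None or r2 > best[2]:
            best = (xc, expo, r2, amp)
    xc, expo, r2, amp = best

    xc_b, ex_b = [], []
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        nblocks = max(1, len(x) // block)
        starts = np.arange(0, len(x) - block + 1) if len(x) > block else np.array([0])
        for _ in range(n_boot):
            idx = np.concatenate([np.arange(s, min(s + block, len(x)))
                                  for s in rng.choice(starts, nblocks)])
            xb, yb = x[idx], y[idx]
            cand_b = candidates[candidates > xb.max()]
            if len(cand_b) == 0 or len(xb) < 6:
                continue
            bb = None
            for c in cand_b:
                e, a, r = _loglog_fit(xb, yb, c)
                if bb is None or r > bb[2]:
                    bb = (c, e, r)
            xc_b.append(bb[0])
            ex_b.append(bb[1])
    return DivergenceFit(critical_value=float(xc), exponent=float(expo),
                         amplitude=float(amp), r_squared=float(r2),
                         window=(float(x.min()), float(x.max())),
                         critical_err=float(np.std(xc_b)) if xc_b else np.nan,
                         exponent_err=float(np.std(ex_b)) if ex_b else np.nan)


def fit_zmax_vs_attraction(eps, z_max, z_c_candidates=None,
                           eps_c_candidates=None, n_boot: int = 0,
                           seed: int | None = None) -> DivergenceFit:
    """Fit z_c − z_max(ε) ∝ (ε_c − ε)^θ over sub-critical attractions.

    Joint grid search over (ε_c, z_c) with OLS for θ at each pair; the
    returned fit carries ε_c as the critical value and θ as the
    exponent, with the selected z_c in ``amplitude``'s companion field
    (see ``extra``).  Warns if z_max is non-monotone in ε beyond 2% of
    its range.
    """
    eps = np.asarray(eps, dtype=float)
    z_max = np.asarray(z_max, dtype=float)
    if len(eps) < 4:
        raise ValueError("need at least 4 sub-critical attraction points")
    order = np.argsort(eps)
    eps, z_max = eps[order], z_max[order]
    if np.any(np.diff(z_max) < -0.02 * np.ptp(z_max)):
        import warnings
        warnings.warn("z_max(eps) is non-monotone beyond noise", stacklevel=2)
    if eps_c_candidates is None:
        span = np.ptp(eps)
        eps_c_candidates = eps.max() + np.linspace(0.01 * span, span, 100)
    if z_c_candidates is None:
        dz = max(np.ptp(z_max), 0.5)
        z_c_candidates = z_max.max() + np.linspace(0.005 * dz, 2.0 * dz, 80)

    best = None
    for zc in z_c_candidates:
        gap = zc - z_max
        if np.any(gap <= 0):
            continue
        for ec in eps_c_candidates:
            lx = np.log(ec - eps)
            ly = np.log(gap)
            slope, intercept = np.polyfit(lx, ly, 1)
            resid = ly - (slope * lx + intercept)
            ss = ((ly - ly.mean()) ** 2).sum()
            r2 = 1.0 - (resid**2).sum() / ss if ss > 0 else 0.0
            if best is None or r2 > best[0]:
                best = (r2, ec, zc, slope, np.exp(intercept))
    if best is None:
        raise ValueError("no admissible (eps_c, z_c) candidate")
    r2, ec, zc, theta, amp = best
    fit = DivergenceFit(critical_value=float(ec), exponent=float(theta),
                        amplitude=float(amp), r_squared=float(r2),
                        window=(float(eps.min()), float(eps.max())))
    object.__setattr__(fit, "z_c", float(zc))
    return fit


def hyperscaling_df(tau: float, d: int = 3) -> float:
    """d_f from the percolation hyperscaling relation τ = d/d_f + 1."""
    if tau <= 1:
        raise ValueError("cluster-mass exponent tau must exceed 1")
    return d / (tau - 1.0)
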