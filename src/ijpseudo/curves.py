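"""Product-limit and IPCW-form functionals of a counting summary.

Estimated curves for a competing-risks sample:

* censoring Nelson--Aalen hazard  L^_0(s) = sum_{u<=s} dH^_0(u)/H^_c(u)
  and its product-limit censoring survival G^;
* cause-specific hazards L^_j and the IPCW-form Aalen--Johansen
  cumulative incidences  F^_j(s) = sum_{u<=s} dH^_j(u)/G^(u-);
* event survival  S^ = 1 - sum_j F^_j  (the convention used throughout,
  so that the denominator S^(s)G^(s) = H^(s+) is consistent between the
  plain and truncation-adjusted paths);
* the reversed-time product-limit estimator of the entry-time
  distribution F_L, normalised to 1 at the largest observed entry tau;
* the rho-mapping that reconstructs (H^, H^_c, H^_j) from (G^, F^_j),
  used by the truncation-modified pseudo-observations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._stepfun import StepFunction
from .core import CountingSummary, Sample, _counting_arrays

__all__ = [
    "CurveSet",
    "TruncationCdf",
    "cumulative_hazard",
    "product_limit",
    "fit_curves",
    "truncation_cdf",
    "rho_map",
    "aalen_johansen",
]


@dataclass
class CurveSet:
    """Estimated curves of a sample on the pooled jump-time grid."""

    G: StepFunction
    S: StepFunction
    F: list
    Lambda0: StepFunction
    LambdaJ: list
    truncation_adjusted: bool = False


@dataclass
class TruncationCdf:
    """Reversed-time product-limit estimate of P(L <= s | L <= tau)."""

    FL: StepFunction
    tau: float


def cumulative_hazard(numerator: StepFunction, at_risk: StepFunction) -> StepFunction:
    """Nelson--Aalen-type hazard sum_{u<=s} dN(u) / R(u).

    ``at_risk`` is evaluated *at* each jump of ``numerator`` (the
    convention appropriate to the specific hazard: the censoring hazard
    uses H^_c(u), event hazards use H^(u)).  A zero risk set at a jump
    with positive increment is an error naming the time.
    """
    u = numerator.x
    dN = np.diff(np.concatenate([[numerator.y0], numerator.y]))
    risk = np.atleast_1d(at_risk(u))
    bad = (dN > 0) & (risk <= 0)
    if np.any(bad):
        raise ZeroDivisionError(
            f"zero risk set at time {u[np.flatnonzero(bad)[0]]:g} "
            "with a positive hazard increment"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        dL = np.where(dN > 0, dN / risk, 0.0)
    return StepFunction(u, np.cumsum(dL), initial_value=0.0)


def product_limit(Lambda: StepFunction) -> StepFunction:
    """Product integral S(s) = prod_{u<=s} (1 - dL(u)); 1 before first jump."""
    dL = np.diff(np.concatenate([[Lambda.y0], Lambda.y]))
    if np.any(dL > 1 + 1e-12):
        raise ValueError("hazard increment exceeds 1; product limit undefined")
    return StepFunction(Lambda.x, np.cumprod(1.0 - np.clip(dL, 0.0, 1.0)),
                        initial_value=1.0)


def _curve_arrays(sample: Sample, truncation_adjusted: bool):
    """Internal: (u, G_at, G_left, F (d+1,K cumulative), S_at, dLambda0) as fractions.

    F[j] for j >= 1 are IPCW-form Aalen--Johansen cumulative incidences;
    row 0 is unused (kept for index alignment).
    """
    u, risk_at, risk_cens_at, d_at = _counting_arrays(sample, truncation_adjusted)
    n = sample.n
    h_cens = risk_cens_at / n
    d0 = d_at[0] / n
    bad = (d0 > 0) & (h_cens <= 0)
    if np.any(bad):
        raise ZeroDivisionError(
            f"censoring at-risk set empty at time {u[np.flatnonzero(bad)[0]]:g}"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        dL0 = np.where(d0 > 0, d0 / h_cens, 0.0)
    G = np.cumprod(1.0 - dL0)
    G_left = np.concatenate([[1.0], G[:-1]])
    F = np.zeros((sample.d + 1, u.size))
    for j in range(1, sample.d + 1):
        dj = d_at[j] / n
        bad = (dj > 0) & (G_left <= 0)
        if np.any(bad):
            raise ZeroDivisionError(
                f"censoring survival G^(u-) = 0 at event time "
                f"{u[np.flatnonzero(bad)[0]]:g}"
            )
        with np.errstate(invalid="ignore", divide="ignore"):
            dF = np.where(dj > 0, dj / G_left, 0.0)
        F[j] = np.cumsum(dF)
    S = 1.0 - F[1:].sum(axis=0)
    return u, G, G_left, F, S, dL0, risk_at / n, d_at


def fit_curves(summary_or_sample, truncation_adjusted: bool = None) -> CurveSet:
    """Estimate (G^, S^, F^_j, L^_0, L^_j) from a sample or its summary.

    S^ is formed as 1 - sum_j F^_j.  Accepts either a :class:`Sample`
    (preferred; the flag defaults to whether the sample is truncated) or
    a :class:`CountingSummary`.
    """
    if isinstance(summary_or_sample, CountingSummary):
        sample = summary_or_sample._sample  # set by callers that keep it
        truncation_adjusted = summary_or_sample.truncation_adjusted
    else:
        sample = summary_or_sample
        if truncation_adjusted is None:
            truncation_adjusted = sample.truncated
    u, G, G_left, F, S, dL0, h_at, d_at = _curve_arrays(sample, truncation_adjusted)
    n = sample.n
    LambdaJ = []
    for j in range(1, sample.d + 1):
        dj = d_at[j] / n
        with np.errstate(invalid="ignore", divide="ignore"):
            dLj = np.where(dj > 0, dj / h_at, 0.0)
        LambdaJ.append(StepFunction(u, np.cumsum(dLj), initial_value=0.0))
    return CurveSet(
        G=StepFunction(u, G, initial_value=1.0),
        S=StepFunction(u, S, initial_value=1.0),
        F=[StepFunction(u, F[j], initial_value=0.0) for j in range(1, sample.d + 1)],
        Lambda0=StepFunction(u, np.cumsum(dL0), initial_value=0.0),
        LambdaJ=LambdaJ,
        truncation_adjusted=bool(truncation_adjusted),
    )


def aalen_johansen(sample: Sample, t: float, cause: int = 1,
                   truncation_adjusted: bool = None) -> float:
    """IPCW-form Aalen--Johansen estimate F^_cause(t)."""
    cs = fit_curves(sample, truncation_adjusted)
    return float(cs.F[cause - 1](t))


def truncation_cdf(sample: Sample) -> TruncationCdf:
    """Reversed-time product-limit estimate of the entry distribution.

    F^_L(s) = prod_{u in (s, tau]} (1 - dL^_L(u)), with the reverse-hazard
    increments dL^_L(u) = dN_L(u) / H^(u) built from the truncation-
    adjusted at-risk average; tau is the largest observed entry time, and
    F^_L(tau) = 1 so the curve estimates P(L <= s | L <= tau).  With all
    entries zero the estimate is identically 1.
    """
    entry = sample.entry
    tau = float(entry.max(initial=0.0))
    if tau <= 0.0:
        return TruncationCdf(FL=StepFunction([], [], initial_value=1.0), tau=0.0)
    atoms = np.unique(entry)
    e_sorted = np.sort(entry)
    t_sorted = np.sort(sample.time)
    n = sample.n
    entered = np.searchsorted(e_sorted, atoms, side="right")
    gone = np.searchsorted(t_sorted, atoms, side="left")
    risk = (entered - gone) / n                      # H^(u) at entry atoms
    dNL = np.diff(np.concatenate([[0], entered])) / n
    if np.any((dNL > 0) & (risk <= 0)):
        bad = atoms[np.flatnonzero((dNL > 0) & (risk <= 0))[0]]
        raise ZeroDivisionError(f"empty at-risk set at entry time {bad:g}")
    dLL = dNL / risk
    if np.any(dLL > 1 + 1e-12):
        raise ValueError("reverse-hazard increment exceeds 1")
    dLL = np.clip(dLL, 0.0, 1.0)
    # F_L(s) for s in [atoms[k], atoms[k+1]) is prod over atoms > s
    # suffix products over atoms k+1..end
    rev = np.cumprod((1.0 - dLL)[::-1])[::-1]        # prod over atoms >= k
    suffix = np.concatenate([rev[1:], [1.0]])        # prod over atoms > k
    fl0 = float(rev[0])                              # value below first atom
    return TruncationCdf(FL=StepFunction(atoms, suffix, initial_value=fl0), tau=tau)


def rho_map(G: StepFunction, F: list) -> CountingSummary:
    """Reconstruct the counting averages from (G^, F^_1..F^_d).

    Implements the second stage of the rho = rho2 o rho1 mapping:
    H^(s) = S^(s-)G^(s-)  (stored right-continuously as S^(s)G^(s)),
    H^_c(s) = S^(s)G^(s-),  H^_0(s) = sum_{u<=s} S^(u) d(1-G^(u)),
    H^_j(s) = sum_{u<=s} G^(u-) dF^_j(u).
    """
    grid = np.unique(np.concatenate([G.x] + [f.x for f in F]))
    Gv = np.atleast_1d(G(grid))
    Gl = np.atleast_1d(G(grid, side="left"))
    Fv = np.array([np.atleast_1d(f(grid)) for f in F])
    Fl = np.array([np.atleast_1d(f(grid, side="left")) for f in F])
    Sv = 1.0 - Fv.sum(axis=0)
    h_after = Sv * Gv
    at_risk = StepFunction(grid, h_after, initial_value=1.0)
    at_risk_cens = StepFunction(grid, Sv * Gl, initial_value=1.0)
    dG = Gl - Gv
    H0 = np.cumsum(Sv * dG)
    counts = [StepFunction(grid, H0, initial_value=0.0)]
    for j in range(len(F)):
        dFj = Fv[j] - Fl[j]
        counts.append(StepFunction(grid, np.cumsum(Gl * dFj), initial_value=0.0))
    return CountingSummary(
        at_risk=at_risk,
        at_risk_cens=at_risk_cens,
        counts=counts,
        truncation_adjusted=False,
        times=grid,
    )
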