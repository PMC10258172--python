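"""Pseudo-observations for cumulative-incidence and survival functionals.

Three flavours are provided, all at a single analysis time t:

* **jackknife** -- theta^_{n,i} = n theta^_n - (n-1) theta^_n^{(i)}, the
  classical leave-one-out pseudo-observation of the Aalen--Johansen
  estimate.  An O(n + m) single-pass algorithm (risk-set downdating with
  prefix/suffix products over the event-time grid) produces all n
  leave-one-out estimates; the naive O(n^2) recomputation is retained as
  an oracle.
* **ij** (infinitesimal jackknife) -- phi(F_n) + phidot_{F_n}(X_i), the
  functional value plus its first-order influence function evaluated at
  the empirical distribution:

      1(T~_i <= t, D~_i = j)/G^(T~_i-)
        + int_0^t (F^_j(t) - F^_j(s)) / (S^(s) G^(s)) dM^_{0i}(s),

  with M^_{0i}(s) = N_{0i}(s) - int_0^s Y_{c,i}(u) dL^_0(u).  All curves
  are computed once from the full sample; the per-subject values are
  exact plug-ins, and their mean equals F^_j(t) to machine precision.
* **ij_truncated** -- the left-truncation modification: curves G^, F^_j
  (and S^ = 1 - sum F^_j) are estimated with truncation-adjusted risk
  sets, while the censoring martingale M^_{0i} uses the *untruncated*
  at-risk indicator Y_{c,i} (every subject at risk from time zero).
  These pseudo-values are paired with inverse-probability-of-sampling
  weights w^_i = 1 / F^_L(min(T~_i, tau)) in the estimating equation.

Pseudo-observations may fall outside [0, 1]; no clipping is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Sample
from .curves import _curve_arrays, truncation_cdf

__all__ = [
    "PseudoSet",
    "jackknife_pseudo",
    "ij_pseudo",
    "ij_pseudo_survival",
    "ij_pseudo_truncated",
    "ipcw_pseudo",
    "sampling_weights",
    "ij_weight_derivative",
    "aalen_johansen_weighted",
    "PseudoObservations",
]


@dataclass
class PseudoSet:
    """Per-subject pseudo-observations at a target time."""

    values: np.ndarray
    t: float
    cause: object                      # event code j, or "survival"
    method: str                        # jackknife | ij | ij_truncated | ipcw
    weights: np.ndarray = None         # sampling weights (all 1 unless truncated)
    base_estimate: float = None        # phi(F_n) at t

    def __post_init__(self):
        if self.weights is None:
            self.weights = np.ones_like(self.values)

    @property
    def n(self) -> int:
        return self.values.shape[0]


# ---------------------------------------------------------------------------
# Infinitesimal jackknife (influence-function plug-in)
# ---------------------------------------------------------------------------

def _ij_values(sample: Sample, t: float, cause: int,
               truncation_adjusted: bool) -> tuple[np.ndarray, float]:
    """Plug-in evaluation of phi(F_n) + phidot(X_i) on the pooled grid.

    With ``truncation_adjusted`` the curves come from delayed-entry risk
    sets while the censoring martingale keeps the untruncated at-risk
    indicator, exactly the truncation modification.
    """
    u, G, G_left, F, S, dL0, _, _ = _curve_arrays(sample, truncation_adjusted)
    Kt = np.searchsorted(u, t, side="right") - 1     # last grid index <= t
    Fj = F[cause]
    Fj_t = Fj[Kt] if Kt >= 0 else 0.0
    H_after = S * G                                   # H^(s+) = S^(s) G^(s)
    cens = dL0 > 0
    need = cens & (np.arange(u.size) <= Kt)
    if np.any(need & (H_after <= 0) & (Fj_t - Fj != 0)):
        bad = u[np.flatnonzero(need & (H_after <= 0))[0]]
        raise ZeroDivisionError(f"S^(s)G^(s) = 0 at censoring time {bad:g} <= t")
    w = np.zeros(u.size)
    with np.errstate(invalid="ignore", divide="ignore"):
        np.divide(Fj_t - Fj, H_after, out=w, where=need & (H_after > 0))
    cw = np.cumsum(w * dL0)                           # int_0^{u_k} w dLambda_0

    idx = np.searchsorted(u, sample.time)             # own-time grid index
    is_event = (sample.status == cause) & (sample.time <= t)
    is_cens = (sample.status == 0) & (sample.time <= t)
    Gm_own = G_left[idx]
    if np.any(is_event & (Gm_own <= 0)):
        raise ZeroDivisionError("G^(T~-) = 0 at an observed event time <= t")
    term1 = np.zeros(sample.n)
    np.divide(1.0, Gm_own, out=term1, where=is_event)
    term2 = np.where(is_cens, w[idx], 0.0)
    # Y_{c,i}(u) = 1 for u < T~_i, and at u = T~_i only when censored
    m = np.where(sample.status == 0, idx, idx - 1)
    m = np.minimum(m, Kt)
    term3 = np.where(m >= 0, cw[np.clip(m, 0, None)], 0.0)
    return term1 + term2 - term3, float(Fj_t)


def ij_pseudo(sample: Sample, t: float, cause: int = 1) -> PseudoSet:
    """Infinitesimal-jackknife pseudo-observations of F_j(t) (no truncation)."""
    if sample.truncated:
        raise ValueError(
            "sample has positive entry times; use ij_pseudo_truncated"
        )
    values, base = _ij_values(sample, t, cause, truncation_adjusted=False)
    return PseudoSet(values=values, t=t, cause=cause, method="ij",
                     base_estimate=base)


def ij_pseudo_survival(sample: Sample, t: float) -> PseudoSet:
    """IJ pseudo-observations of the survival probability S(t) = 1 - sum_j F_j(t)."""
    total = np.zeros(sample.n)
    base = 0.0
    trunc = sample.truncated
    for j in range(1, sample.d + 1):
        vals, b = _ij_values(sample, t, j, truncation_adjusted=trunc)
        total += vals
        base += b
    weights = sampling_weights(sample) if trunc else None
    return PseudoSet(values=1.0 - total, t=t, cause="survival",
                     method="ij_truncated" if trunc else "ij",
                     weights=weights, base_estimate=1.0 - base)


def ij_pseudo_truncated(sample: Sample, t: float, cause: int = 1) -> PseudoSet:
    """Truncation-modified IJ pseudo-observations with sampling weights.

    On a sample with all entries zero this reduces exactly to
    :func:`ij_pseudo` with unit weights.
    """
    values, base = _ij_values(sample, t, cause,
                              truncation_adjusted=sample.truncated)
    weights = sampling_weights(sample)
    return PseudoSet(values=values, t=t, cause=cause, method="ij_truncated",
                     weights=weights, base_estimate=base)


def ipcw_pseudo(sample: Sample, t: float, cause: int = 1) -> PseudoSet:
    """IPCW responses 1(T~<=t, D~=j)/G^(T~-): the first term of the IJ formula.

    The comparator used by direct binomial regression; its mean is the
    IPCW-form Aalen--Johansen estimate F^_j(t).
    """
    u, G, G_left, F, S, dL0, _, _ = _curve_arrays(
        sample, truncation_adjusted=sample.truncated)
    Kt = np.searchsorted(u, t, side="right") - 1
    base = float(F[cause][Kt]) if Kt >= 0 else 0.0
    idx = np.searchsorted(u, sample.time)
    is_event = (sample.status == cause) & (sample.time <= t)
    Gm = G_left[idx]
    if np.any(is_event & (Gm <= 0)):
        raise ZeroDivisionError("G^(T~-) = 0 at an observed event time <= t")
    values = np.zeros(sample.n)
    np.divide(1.0, Gm, out=values, where=is_event)
    return PseudoSet(values=values, t=t, cause=cause, method="ipcw",
                     base_estimate=base)


def sampling_weights(sample: Sample) -> np.ndarray:
    """Inverse-probability-of-sampling weights w^_i = 1/F^_L(min(T~_i, tau)).

    All ones when no subject has a positive entry time.  Subjects with
    follow-up beyond tau (the largest observed entry) receive the
    tau-conditional weight 1.  A zero F^_L at some subject's follow-up
    time is an error naming the subject.
    """
    if not sample.truncated:
        return np.ones(sample.n)
    tc = truncation_cdf(sample)
    fl = np.atleast_1d(tc.FL(np.minimum(sample.time, tc.tau)))
    if np.any(fl <= 0):
        bad = int(np.flatnonzero(fl <= 0)[0])
        raise ZeroDivisionError(
            f"subject {bad}: estimated truncation CDF is 0 at its follow-up "
            f"time {sample.time[bad]:g}; sampling weight undefined"
        )
    return 1.0 / fl


# ---------------------------------------------------------------------------
# Jackknife (leave-one-out) pseudo-observations
# ---------------------------------------------------------------------------

def _event_grid(sample: Sample, t: float, truncation_adjusted: bool):
    """Event-time grid <= t with risk-set and event counts (integers).

    The hazard-form Aalen--Johansen estimate at t only involves jumps at
    event times <= t, so the leave-one-out pass is restricted to them.
    """
    ev = sample.status >= 1
    u = np.unique(sample.time[ev & (sample.time <= t)])
    t_sorted = np.sort(sample.time)
    below = np.searchsorted(t_sorted, u, side="left")
    if truncation_adjusted:
        entered = np.searchsorted(np.sort(sample.entry), u, side="right")
    else:
        entered = np.full(u.shape, sample.n)
    r = (entered - below).astype(float)
    dall = np.zeros(u.size)
    d1 = np.zeros(u.size)
    idx = np.searchsorted(u, sample.time)
    sel = ev & (sample.time <= t)
    np.add.at(dall, idx[sel], 1)
    return u, r, dall, d1, idx  # d1 filled per cause by caller


def _aj_from_grid(r, dall, d1):
    """Hazard-form AJ value sum_k S_{k-1} d1_k/r_k from count arrays."""
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(r > 0, 1.0 - dall / r, 1.0)
        a1 = np.where(r > 0, d1 / r, 0.0)
    S_prev = np.concatenate([[1.0], np.cumprod(f)[:-1]])
    return float(np.sum(S_prev * a1))


def _loo_direct(u, r, dall, d1, entry_i, time_i, own_all, own_1):
    """Leave-one-out AJ by direct recomputation (fallback path)."""
    in_win = (u >= entry_i) & (u <= time_i)
    r2 = r - in_win
    dall2 = dall.copy()
    d12 = d1.copy()
    if own_all:
        k = np.searchsorted(u, time_i)
        dall2[k] -= 1
        if own_1:
            d12[k] -= 1
    return _aj_from_grid(r2, dall2, d12)


def _jackknife_loo(sample: Sample, t: float, cause: int,
                   truncation_adjusted: bool) -> tuple[np.ndarray, float]:
    """All leave-one-out AJ estimates in one pass, plus the full estimate.

    Risk sets are downdated over each subject's at-risk window
    [L_i, T~_i] on the event grid; prefix products of the downdated
    hazard factors and a suffix recursion for the post-window remainder
    give every leave-one-out estimate in O(n + m).
    """
    u, r, dall, d1, idx_all = _event_grid(sample, t, truncation_adjusted)
    K = u.size
    sel1 = (sample.status == cause) & (sample.time <= t)
    np.add.at(d1, idx_all[sel1], 1)
    full = _aj_from_grid(r, dall, d1)
    if K == 0:
        return np.full(sample.n, full), full

    f = 1.0 - dall / r
    S = np.cumprod(f)
    S_prev = np.concatenate([[1.0], S[:-1]])
    C = np.cumsum(S_prev * d1 / r)
    # suffix D_k = sum_{l>k} (prod_{m=k+1}^{l-1} f_m) d1_l/r_l
    D = np.zeros(K)
    if np.all(S > 0):
        D = (C[-1] - C) / S
    else:  # a hazard factor hit zero: backward recursion instead of division
        acc = 0.0
        for k in range(K - 1, 0, -1):
            acc = d1[k] / r[k] + f[k] * acc
            D[k - 1] = acc
        D[K - 1] = 0.0

    r1 = r - 1.0
    pos = r1 > 0
    g = np.where(pos, 1.0 - dall / np.where(pos, r1, 1.0), 1.0)
    h = np.where(pos, d1 / np.where(pos, r1, 1.0), 0.0)
    P = np.cumprod(g)
    P_prev = np.concatenate([[1.0], P[:-1]])
    Atil = np.cumsum(P_prev * h)

    time_i, entry_i = sample.time, sample.entry
    b = np.searchsorted(u, time_i, side="right") - 1
    a = np.searchsorted(u, entry_i, side="left")
    own_all = (sample.status >= 1) & (time_i <= t)
    own_1 = sel1

    loo = np.full(sample.n, full)
    act = a <= b                       # window overlaps the grid
    ai, bi = a[act], b[act]
    Pa = np.where(ai > 0, P[np.clip(ai - 1, 0, None)], 1.0)
    Aa = np.where(ai > 0, Atil[np.clip(ai - 1, 0, None)], 0.0)
    Sa = np.where(ai > 0, S[np.clip(ai - 1, 0, None)], 1.0)
    Ca = np.where(ai > 0, C[np.clip(ai - 1, 0, None)], 0.0)
    ok = Pa > 0
    Pb_prev = np.where(bi > 0, P[np.clip(bi - 1, 0, None)], 1.0)
    rb1 = r1[bi]
    oa = own_all[act]
    o1 = own_1[act]
    with np.errstate(invalid="ignore", divide="ignore"):
        mid = (Atil[bi] - Aa) / Pa
        mid -= np.where(o1 & (rb1 > 0), (Pb_prev / Pa) / np.where(rb1 > 0, rb1, 1.0), 0.0)
        gb = np.where(rb1 > 0,
                      1.0 - (dall[bi] - oa) / np.where(rb1 > 0, rb1, 1.0), 1.0)
        tail = (Pb_prev / Pa) * gb * D[bi]
    vals = Ca + Sa * (mid + tail)
    loo_act = np.where(ok, vals, np.nan)
    # rare fallback: a zero prefix product inside the division window
    if np.any(~ok):
        act_idx = np.flatnonzero(act)
        for pos in np.flatnonzero(~ok):
            i = act_idx[pos]
            loo_act[pos] = _loo_direct(u, r, dall, d1, entry_i[i], time_i[i],
                                       own_all[i], own_1[i])
    loo[act] = loo_act
    return loo, full


def jackknife_pseudo(sample: Sample, t: float, cause: int = 1,
                     algorithm: str = "efficient") -> PseudoSet:
    """Jackknife pseudo-observations n*theta^ - (n-1)*theta^(i) of F_j(t).

    On a truncated sample the base estimate uses truncation-adjusted
    risk sets (the literature practice whose bias the truncation-modified
    IJ corrects); no sampling weights are attached.
    ``algorithm='naive'`` recomputes the Aalen--Johansen estimate n+1
    times and serves as the oracle for the single-pass path.
    """
    n = sample.n
    if n < 2:
        raise ValueError("jackknife requires at least 2 subjects")
    adj = sample.truncated
    if algorithm == "efficient":
        loo, full = _jackknife_loo(sample, t, cause, adj)
    elif algorithm == "naive":
        u, r, dall, d1, idx_all = _event_grid(sample, t, adj)
        sel1 = (sample.status == cause) & (sample.time <= t)
        np.add.at(d1, idx_all[sel1], 1)
        full = _aj_from_grid(r, dall, d1)
        own_all = (sample.status >= 1) & (sample.time <= t)
        loo = np.array([
            _loo_direct(u, r, dall, d1, sample.entry[i], sample.time[i],
                        own_all[i], sel1[i])
            for i in range(n)
        ])
    else:
        raise ValueError("algorithm must be 'efficient' or 'naive'")
    values = n * full - (n - 1) * loo
    return PseudoSet(values=values, t=t, cause=cause, method="jackknife",
                     base_estimate=full)


# ---------------------------------------------------------------------------
# Weighted estimator and its analytic weight derivative (dfbeta surface)
# ---------------------------------------------------------------------------

def aalen_johansen_weighted(sample: Sample, t: float, cause: int,
                            weights: np.ndarray) -> float:
    """Hazard-form AJ estimate with per-subject weights (no truncation).

    F^w_j(t) = sum_k S^w(u_k-) dL^w_j(u_k) with S^w the product integral
    of the total weighted event hazard.  Used for finite-difference
    influence computations; equals the unweighted estimate at equal
    weights.
    """
    w = np.asarray(weights, dtype=float)
    ev = (sample.status >= 1) & (sample.time <= t)
    u = np.unique(sample.time[ev])
    if u.size == 0:
        return 0.0
    order = np.argsort(sample.time, kind="stable")
    ts, ws = sample.time[order], w[order]
    csum = np.concatenate([[0.0], np.cumsum(ws)])
    total = csum[-1]
    below = np.searchsorted(ts, u, side="left")
    rw = total - csum[below]                      # sum of w_i with T~_i >= u_k
    idx = np.searchsorted(u, sample.time)
    dallw = np.zeros(u.size)
    d1w = np.zeros(u.size)
    np.add.at(dallw, idx[ev], w[ev])
    sel1 = ev & (sample.status == cause)
    np.add.at(d1w, idx[sel1], w[sel1])
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(rw > 0, 1.0 - dallw / rw, 1.0)
        a1 = np.where(rw > 0, d1w / rw, 0.0)
    S_prev = np.concatenate([[1.0], np.cumprod(f)[:-1]])
    return float(np.sum(S_prev * a1))


def ij_weight_derivative(sample: Sample, t: float, cause: int = 1) -> PseudoSet:
    """Analytic dfbeta form of the IJ pseudo-observations.

    Extends the hazard-form Aalen--Johansen estimate to subject weights
    w_i and differentiates with respect to each subject's own weight at
    equal weights 1/n, returning phi(F_n) + dF^w_j(t)/dw_i.  The product-
    integral survival (1 - dL per jump) is used so this surface matches
    the influence-function plug-in :func:`ij_pseudo` to machine
    precision.
    """
    if sample.truncated:
        raise ValueError("weight-derivative path is defined for untruncated samples")
    n = sample.n
    ev = (sample.status >= 1) & (sample.time <= t)
    u = np.unique(sample.time[ev])
    K = u.size
    if K == 0:
        return PseudoSet(values=np.zeros(n), t=t, cause=cause,
                         method="ij_weight_derivative", base_estimate=0.0)
    t_sorted = np.sort(sample.time)
    rw = (n - np.searchsorted(t_sorted, u, side="left")) / n
    idx = np.searchsorted(u, sample.time)
    dallw = np.zeros(K)
    d1w = np.zeros(K)
    np.add.at(dallw, idx[ev], 1.0 / n)
    sel1 = ev & (sample.status == cause)
    np.add.at(d1w, idx[sel1], 1.0 / n)
    lam_all = dallw / rw
    lam1 = d1w / rw
    f = 1.0 - lam_all
    S_prev = np.concatenate([[1.0], np.cumprod(f)[:-1]])
    terms = S_prev * lam1                           # AJ increments
    full = float(terms.sum())
    V = np.cumsum(terms)                            # V_k = sum_{l<=k} terms
    # cum_k = sum_{l<=k} lam_all_l / (rw_l (1 - lam_all_l))
    cum = np.cumsum(lam_all / (rw * f))
    cum0 = np.concatenate([[0.0], cum])             # cum0[k] = cum_{k-1}
    U = np.cumsum(terms * cum0[:-1])                # U_k = sum_{l<=k} terms_l cum_{l-1}

    j_i = np.searchsorted(u, sample.time, side="right") - 1   # last u_k <= T~_i
    at_risk_any = j_i >= 0
    jc = np.clip(j_i, 0, K - 1)
    Vj = np.where(at_risk_any, V[jc], 0.0)
    sumA = -np.where(at_risk_any, np.cumsum(terms / rw)[jc], 0.0)
    own1 = sel1
    ownE = ev
    e = idx
    sumA += np.where(own1, S_prev[np.clip(e, 0, K - 1)] / rw[np.clip(e, 0, K - 1)], 0.0)

    # B term: -ownE * q_e * (V_K - V_e) + [U_{min(j+1,K)} + cum_j (V_K - V_{min(j+1,K)})]
    q = 1.0 / (rw * f)
    ec = np.clip(e, 0, K - 1)
    B = -np.where(ownE, q[ec] * (V[-1] - V[ec]), 0.0)
    jp1 = np.clip(j_i + 1, 0, K)                     # index into 1-based prefix
    V0 = np.concatenate([[0.0], V])
    U0 = np.concatenate([[0.0], U])
    cumj = np.where(at_risk_any, cum[jc], 0.0)
    B += U0[jp1] + cumj * (V[-1] - V0[jp1])
    deriv = sumA + B
    return PseudoSet(values=full + deriv, t=t, cause=cause,
                     method="ij_weight_derivative", base_estimate=full)


# ---------------------------------------------------------------------------
# sklearn-style transformer
# ---------------------------------------------------------------------------

from sklearn.base import BaseEstimator, TransformerMixin  # noqa: E402

from .io import frame_to_sample  # noqa: E402


class PseudoObservations(BaseEstimator, TransformerMixin):
    """Transformer mapping subject records to pseudo-observation vectors.

    Parameters
    ----------
    t : float
        Analysis time.
    cause : int or "survival"
        Event type of the cumulative incidence, or "survival" for S(t).
    method : {"ij", "jackknife", "ij_truncated", "ipcw"}
        Pseudo-observation flavour; "ij_truncated" attaches inverse
        sampling weights (exposed as ``weights_``).
    algorithm : {"efficient", "naive"}
        Leave-one-out strategy for the jackknife.

    After ``fit`` the attributes ``pseudo_values_``, ``weights_`` and
    ``base_estimate_`` are available; ``transform`` returns the pseudo
    values as a column vector.
    """

    def __init__(self, t: float = 1.0, cause=1, method: str = "ij",
                 algorithm: str = "efficient"):
        self.t = t
        self.cause = cause
        self.method = method
        self.algorithm = algorithm

    def _compute(self, sample: Sample) -> PseudoSet:
        if self.cause == "survival":
            if self.method not in ("ij", "ij_truncated"):
                raise ValueError("survival pseudo-values use the IJ method")
            return ij_pseudo_survival(sample, self.t)
        if self.method == "ij":
            return ij_pseudo(sample, self.t, self.cause)
        if self.method == "ij_truncated":
            return ij_pseudo_truncated(sample, self.t, self.cause)
        if self.method == "jackknife":
            return jackknife_pseudo(sample, self.t, self.cause, self.algorithm)
        if self.method == "ipcw":
            return ipcw_pseudo(sample, self.t, self.cause)
        raise ValueError(f"unknown method {self.method!r}")

    def fit(self, X, y=None):
        sample = X if isinstance(X, Sample) else frame_to_sample(X)
        ps = self._compute(sample)
        self.pseudo_set_ = ps
        self.pseudo_values_ = ps.values
        self.weights_ = ps.weights
        self.base_estimate_ = ps.base_estimate
        self.n_features_in_ = 1
        return self

    def transform(self, X=None):
        """Return the fitted pseudo-observations as an (n, 1) array."""
        if not hasattr(self, "pseudo_values_"):
            raise RuntimeError("PseudoObservations is not fitted")
        return self.pseudo_values_.reshape(-1, 1)

    def fit_transform(self, X, y=None, **fit_params):
        return self.fit(X, y).transform(X)
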