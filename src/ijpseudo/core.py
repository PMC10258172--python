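"""Subject-level data container and counting-process summaries.

The unit of computation throughout the package is a :class:`Sample` of
right-censored, possibly left-truncated competing-risks records
``(entry L_i, follow-up time T~_i, status D~_i, covariates Z_i)`` with
status 0 meaning censored and 1..d the event causes.

:func:`empirical_summary` turns a sample into the empirical averages of
its counting-process representation: the at-risk average H^(s), the
censoring at-risk average H^_c(s) (whose definition handles tied event
and censoring times by letting events precede censorings), and the
subdistribution counts H^_j(s), j = 0..d.  These averages are the
"empirical distribution" F_n of which every estimator in the package is
a functional.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._stepfun import StepFunction

__all__ = ["Sample", "CountingSummary", "make_sample", "empirical_summary"]


@dataclass(frozen=True)
class Sample:
    """Validated subject-level time-to-event data.

    Attributes
    ----------
    time : ndarray
        Observed follow-up times T~_i = min(T_i, C_i), all > 0.
    status : ndarray of int
        Event codes D~_i in {0, 1, ..., d}; 0 = censored.
    entry : ndarray
        Left-truncation (delayed-entry) times L_i >= 0, with L_i <= T~_i.
    covariates : ndarray, shape (n, k)
        Numeric covariate matrix Z (no missing values).
    d : int
        Number of event causes.
    """

    time: np.ndarray
    status: np.ndarray
    entry: np.ndarray
    covariates: np.ndarray
    d: int

    @property
    def n(self) -> int:
        return self.time.shape[0]

    @property
    def truncated(self) -> bool:
        """True when any subject has a positive entry time."""
        return bool(np.any(self.entry > 0))

    def subset(self, idx) -> "Sample":
        """Return the sample restricted (or resampled) to ``idx``."""
        return Sample(
            time=self.time[idx],
            status=self.status[idx],
            entry=self.entry[idx],
            covariates=self.covariates[idx],
            d=self.d,
        )


def make_sample(time, status, entry=None, covariates=None, d=None) -> Sample:
    """Validate raw arrays into a :class:`Sample`.

    ``entry=None`` means no delayed entry (all zeros).  ``d`` defaults to
    the largest observed status code (at least 1).

    Raises
    ------
    ValueError
        On mismatched lengths, status codes outside {0..d}, non-positive
        times, negative entries, entry > time (the offending row is
        named), or missing covariate values.
    """
    time = np.asarray(time, dtype=float).ravel()
    status = np.asarray(status).ravel()
    n = time.shape[0]
    if not np.issubdtype(status.dtype, np.integer):
        status_f = np.asarray(status, dtype=float)
        if np.any(status_f != np.round(status_f)):
            raise ValueError("status codes must be integers")
        status = status_f.astype(int)
    else:
        status = status.astype(int)
    if status.shape[0] != n:
        raise ValueError(f"length mismatch: {n} times but {status.shape[0]} statuses")
    if entry is None:
        entry = np.zeros(n)
    else:
        entry = np.asarray(entry, dtype=float).ravel()
        if entry.shape[0] != n:
            raise ValueError(f"length mismatch: {n} times but {entry.shape[0]} entries")
    if covariates is None:
        covariates = np.empty((n, 0))
    else:
        covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
        if covariates.shape[0] == 1 and n > 1:
            covariates = covariates.T
        if covariates.shape[0] != n:
            raise ValueError(
                f"covariates have {covariates.shape[0]} rows but n = {n}"
            )
    if np.any(~np.isfinite(time)) or np.any(time <= 0):
        bad = int(np.flatnonzero(~np.isfinite(time) | (time <= 0))[0])
        raise ValueError(f"row {bad}: follow-up time must be finite and > 0")
    if np.any(entry < 0):
        bad = int(np.flatnonzero(entry < 0)[0])
        raise ValueError(f"row {bad}: entry time must be >= 0")
    if np.any(entry > time):
        bad = int(np.flatnonzero(entry > time)[0])
        raise ValueError(
            f"row {bad}: entry time {entry[bad]:g} exceeds follow-up time "
            f"{time[bad]:g} (left-truncation requires L <= T)"
        )
    if np.any(~np.isfinite(covariates)):
        raise ValueError("covariates contain missing or non-finite values")
    smax = int(status.max(initial=0))
    if d is None:
        d = max(smax, 1)
    if smax > d or int(status.min(initial=0)) < 0:
        raise ValueError(f"status codes must lie in 0..{d}")
    return Sample(time=time, status=status, entry=entry, covariates=covariates, d=int(d))


@dataclass
class CountingSummary:
    """Empirical counting-process averages on the pooled jump-time grid.

    ``at_risk`` stores the right-continuous version s -> H^(s+); because
    H^ itself is left-continuous, its at-value is recovered as the left
    limit: ``at_risk(s, side='left') == H^(s)``.  ``at_risk_cens`` stores
    the censoring at-risk average with value-at-jump equal to H^_c(u_k)
    exactly at every stored jump (the only locations where it enters a
    hazard increment); between jumps it coincides with H^(s+).
    ``counts[j]`` is the right-continuous subdistribution average
    H^_j(s), j = 0..d.
    """

    at_risk: StepFunction
    at_risk_cens: StepFunction
    counts: list
    truncation_adjusted: bool = False
    times: np.ndarray = field(default=None, repr=False)

    @property
    def d(self) -> int:
        return len(self.counts) - 1


def _counting_arrays(sample: Sample, truncation_adjusted: bool):
    """Raw count arrays at the pooled unique observed times.

    Returns (times u_k, risk_at, risk_cens_at, dcounts) where risk_at[k]
    is the number at risk AT u_k (the left limit of the right-continuous
    representation), risk_cens_at[k] the censoring at-risk count at u_k,
    and dcounts[j][k] the number of type-j exits exactly at u_k.  Counts,
    not fractions.
    """
    t = sample.time
    u = np.unique(t)
    n = sample.n
    t_sorted = np.sort(t)
    # number with T~ < u_k  /  T~ <= u_k
    below = np.searchsorted(t_sorted, u, side="left")
    upto = np.searchsorted(t_sorted, u, side="right")
    if truncation_adjusted:
        e_sorted = np.sort(sample.entry)
        entered = np.searchsorted(e_sorted, u, side="right")  # L <= u_k
    else:
        entered = np.full(u.shape, n)
    risk_at = entered - below          # {L <= u_k <= T~}
    d_at = np.zeros((sample.d + 1, u.size))
    idx = np.searchsorted(u, t)
    for j in range(sample.d + 1):
        np.add.at(d_at[j], idx[sample.status == j], 1)
    # censoring at-risk: {L <= u, u < T~} + {L <= u, u = T~, status 0}
    risk_cens_at = (entered - upto) + d_at[0]
    return u, risk_at.astype(float), risk_cens_at.astype(float), d_at


def empirical_summary(sample: Sample, truncation_adjusted: bool = False) -> CountingSummary:
    """Empirical averages (H^, H^_c, H^_0..H^_d) of a sample.

    With ``truncation_adjusted`` the at-risk sets start at each subject's
    entry time; on a sample with all entries zero the flag is a no-op.
    """
    u, risk_at, risk_cens_at, d_at = _counting_arrays(sample, truncation_adjusted)
    n = sample.n
    # at_risk holds H^(s+): drop the at-value by the exits at u_k; with
    # truncation the step function also rises at entry times, so pool them.
    if truncation_adjusted and sample.truncated:
        grid = np.unique(np.concatenate([u, sample.entry]))
        e_sorted = np.sort(sample.entry)
        t_sorted = np.sort(sample.time)
        entered = np.searchsorted(e_sorted, grid, side="right")
        gone = np.searchsorted(t_sorted, grid, side="right")
        h_after = (entered - gone) / n
        at_risk = StepFunction(grid, h_after, initial_value=0.0)
    else:
        t_sorted = np.sort(sample.time)
        h_after = (n - np.searchsorted(t_sorted, u, side="right")) / n
        init = 1.0 if not truncation_adjusted else float(np.mean(sample.entry <= 0))
        at_risk = StepFunction(u, h_after, initial_value=init)
    at_risk_cens = StepFunction(u, risk_cens_at / n, initial_value=at_risk.y0)
    counts = [StepFunction(u, np.cumsum(d_at[j]) / n, initial_value=0.0)
              for j in range(sample.d + 1)]
    cs = CountingSummary(
        at_risk=at_risk,
        at_risk_cens=at_risk_cens,
        counts=counts,
        truncation_adjusted=truncation_adjusted,
        times=u,
    )
    cs._sample = sample  # retained so curve fitting can reuse the raw records
    return cs


def step_eval(f: StepFunction, s, side: str = "right"):
    """Evaluate a :class:`StepFunction` (module-level convenience)."""
    return f(s, side=side)
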