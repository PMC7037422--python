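"""Four-parameter log-logistic (LL4 / 4PL) dose-response modelling.

The response here is a mortality fraction in [0, 1] as a function of a
non-negative dose.  The curve is parameterised as

    f(d) = lower + (upper - lower) / (1 + (ed50 / d) ** shape),   d > 0
    f(0) = lower

with ``lower``/``upper`` the asymptotic responses at zero and infinite
dose, ``ed50`` the dose giving the halfway response and ``shape`` > 0 a
steepness parameter.  For ``shape`` > 0 and ``upper`` > ``lower`` the
curve is strictly increasing, which removes the sign ambiguity of the
slope coefficient in the common b/c/d/e parameterisation.  Dose 0 is a
legitimate data point handled through the analytic limit, never through
``log(0)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "LL4Params",
    "DoseResponseData",
    "LL4Fit",
    "ll4_predict",
    "fit_ll4",
    "ed50",
]


@dataclass(frozen=True)
class LL4Params:
    """LL4 coefficients: asymptotes in [0, 1], ed50 > 0, shape > 0."""

    lower: float
    upper: float
    ed50: float
    shape: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.lower <= 1.0):
            raise ValueError(f"lower asymptote must be in [0, 1], got {self.lower}")
        if not (0.0 <= self.upper <= 1.0):
            raise ValueError(f"upper asymptote must be in [0, 1], got {self.upper}")
        if not self.ed50 > 0:
            raise ValueError(f"ed50 must be > 0, got {self.ed50}")
        if not self.shape > 0:
            raise ValueError(f"shape must be > 0, got {self.shape}")

    def as_array(self) -> np.ndarray:
        return np.array([self.lower, self.upper, self.ed50, self.shape])


@dataclass
class DoseResponseData:
    """Tidy dose-response observations: doses (µg/cm²) and mortality fractions."""

    doses: np.ndarray
    responses: np.ndarray
    replicate_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.doses.shape != self.responses.shape:
            raise ValueError("doses and responses must have equal length")
        if np.any(self.doses < 0):
            raise ValueError("doses must be >= 0")
        if not np.all(np.isfinite(self.responses)):
            raise ValueError("responses must be finite")
        if np.any((self.responses < 0) | (self.responses > 1)):
            raise ValueError("responses must be mortality fractions in [0, 1]")

    @property
    def n_distinct_doses(self) -> int:
        return int(np.unique(self.doses).size)


@dataclass
class LL4Fit:
    """Result of an LL4 least-squares fit with basic diagnostics."""

    params: LL4Params
    sse: float
    converged: bool
    degenerate: bool = False
    n_obs: int = 0

    def predict(self, dose) -> np.ndarray:
        return ll4_predict(dose, self.params)


def ll4_predict(dose, p: LL4Params):
    """Evaluate the LL4 curve at ``dose`` (scalar or array), in [lower, upper]."""
    d = np.asarray(dose, dtype=float)
    if np.any(d < 0):
        raise ValueError("dose must be >= 0")
    out = np.full(d.shape, p.lower, dtype=float)
    pos = d > 0
    if np.any(pos):
        # evaluate the dose ratio in log space; an overflowing ratio just
        # pins the response to the nearer asymptote
        with np.errstate(over="ignore"):
            ratio = np.exp(p.shape * (np.log(p.ed50) - np.log(d[pos])))
            out[pos] = p.lower + (p.upper - p.lower) / (1.0 + ratio)
    if np.isscalar(dose) or np.ndim(dose) == 0:
        return float(out)
    return out


def _residuals(theta: np.ndarray, doses: np.ndarray, responses: np.ndarray) -> np.ndarray:
    lower, upper, log_ed50, log_shape = theta
    ed50_ = np.exp(log_ed50)
    shape_ = np.exp(log_shape)
    pred = np.full_like(doses, lower)
    pos = doses > 0
    pred[pos] = lower + (upper - lower) / (1.0 + (ed50_ / doses[pos]) ** shape_)
    return pred - responses


def _initial_guesses(data: DoseResponseData, n_starts: int, rng: np.random.Generator):
    """Heuristic start: asymptotes from response range, ed50 by interpolation."""
    doses, resp = data.doses, data.responses
    lo = float(np.clip(resp.min(), 0.0, 1.0))
    hi = float(np.clip(resp.max(), 0.0, 1.0))
    half = (lo + hi) / 2.0
    order = np.argsort(doses)
    d_sorted, r_sorted = doses[order], resp[order]
    # first dose whose response crosses the halfway level
    above = np.nonzero(r_sorted >= half)[0]
    if above.size and above[0] > 0:
        i = above[0]
        d0, d1 = d_sorted[i - 1], d_sorted[i]
        r0, r1 = r_sorted[i - 1], r_sorted[i]
        frac = 0.0 if r1 == r0 else (half - r0) / (r1 - r0)
        ed50_0 = d0 + frac * (d1 - d0)
    else:
        ed50_0 = float(np.median(d_sorted[d_sorted > 0]))
    ed50_0 = max(ed50_0, 1e-3)
    guesses = [np.array([lo, hi, np.log(ed50_0), 0.0])]
    for _ in range(max(0, n_starts - 1)):
        jitter = rng.normal(0.0, [0.05, 0.05, 0.5, 0.5])
        g = guesses[0] + jitter
        g[0] = np.clip(g[0], 0.0, 1.0)
        g[1] = np.clip(g[1], 0.0, 1.0)
        guesses.append(g)
    return guesses


def fit_ll4(
    data: DoseResponseData,
    bounds: tuple | None = None,
    n_starts: int = 5,
    seed: int | None = 0,
) -> LL4Fit:
    """Fit LL4 parameters by multi-start bounded least squares.

    Asymptotes are constrained to [0, 1]; ed50 and shape are optimised in
    log space to keep them positive.  The lowest-SSE solution across
    ``n_starts`` deterministic restarts is returned.  A flat response
    profile yields a flagged degenerate fit (``lower ~ upper``) rather
    than an error.

    Parameters
    ----------
    bounds : ((lower_lo, upper_lo, ed50_lo, shape_lo), (..hi..)), optional
        Box bounds on the natural-scale parameters.
    """
    if data.n_distinct_doses < 4:
        raise ValueError(
            f"LL4 fitting needs >= 4 distinct doses, got {data.n_distinct_doses}"
        )
    doses = data.doses
    resp = data.responses
    rng = np.random.default_rng(seed)

    if bounds is None:
        lo_nat = (0.0, 0.0, 1e-4, 1e-3)
        hi_nat = (1.0, 1.0, 1e6, 50.0)
    else:
        lo_nat, hi_nat = bounds
    lo_t = np.array([lo_nat[0], lo_nat[1], np.log(lo_nat[2]), np.log(lo_nat[3])])
    hi_t = np.array([hi_nat[0], hi_nat[1], np.log(hi_nat[2]), np.log(hi_nat[3])])

    # Degenerate data: constant response has no identifiable ed50/shape.
    if np.ptp(resp) < 1e-12:
        c = float(np.clip(resp[0], 0.0, 1.0))
        params = LL4Params(c, c, float(np.median(doses[doses > 0]) or 1.0), 1.0)
        warnings.warn("constant responses: degenerate LL4 fit (lower == upper)")
        return LL4Fit(params, sse=0.0, converged=True, degenerate=True, n_obs=resp.size)

    best = None
    any_converged = False
    for g in _initial_guesses(data, n_starts, rng):
        g = np.clip(g, lo_t, hi_t)
        try:
            res = least_squares(
                _residuals, g, bounds=(lo_t, hi_t), args=(doses, resp), xtol=1e-14,
                ftol=1e-14, gtol=1e-14,
            )
        except Exception:
            continue
        sse = float(np.sum(res.fun**2))
        any_converged = any_converged or bool(res.success)
        if best is None or sse < best[0]:
            best = (sse, res.x, bool(res.success))
    if best is None:
        raise RuntimeError("LL4 fit failed from every start point")

    sse, theta, success = best
    lower, upper = float(np.clip(theta[0], 0, 1)), float(np.clip(theta[1], 0, 1))
    params = LL4Params(lower, upper, float(np.exp(theta[2])), float(np.exp(theta[3])))
    degenerate = abs(upper - lower) < 1e-6
    if not success and not any_converged:
        warnings.warn("LL4 fit did not report convergence; returning best effort")
    return LL4Fit(
        params, sse=sse, converged=success or any_converged,
        degenerate=degenerate, n_obs=resp.size,
    )


def ed50(p: LL4Params) -> float:
    """Dose at which the response is halfway between the asymptotes."""
    if abs(p.upper - p.lower) < 1e-12:
        raise ValueError("ed50 undefined for a flat curve (lower == upper)")
    return p.ed50
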