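"""Independent-action null model and coefficient-distance synergy scoring.

The question: does a nanomaterial make irradiated cells die more than the
two insults would independently?  The null model is Bliss independence —
if the nanomaterial alone kills a fraction ``p_nm(d)`` and irradiation
alone kills ``q`` of the cells that the baseline does not, the combined
mortality under "no interaction" is

    p_sim(d) = 1 - (1 - p_nm(d)) * (1 - q).

``q`` (the *IR impulse*) is the conditional kill of irradiation beyond
baseline, estimated from the dose-0 controls:
``q = (p_ir_ctrl - p_ni_ctrl) / (1 - p_ni_ctrl)``.  Transferring this
impulse onto every non-irradiated condition yields a theoretical
"NM alone + IR alone" dose-response, which is fitted with the same LL4
model as the observed irradiated response.  Divergence is scored as the
Euclidean distance between the two coefficient vectors
``(lower, upper, ln ed50, shape)`` — ed50 on the log scale so its units
cannot dominate the norm — with a sign from the mean observed-minus-
simulated mortality over the nonzero doses (positive = synergy,
negative = antagonism or saturation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .doseresponse import DoseResponseData, LL4Fit, LL4Params, fit_ll4

__all__ = [
    "SynergyResult",
    "ir_impulse",
    "transfer_impulse",
    "simulate_ir_curve",
    "coefficient_distance",
    "synergy_call",
    "synergy_heatmap",
    "null_distance_tolerance",
]

#: Mean per-dose delta below which the sign is called 0 (no direction).
SIGN_TOLERANCE = 0.005


@dataclass
class SynergyResult:
    """Observed vs independent-action-simulated irradiated response."""

    q_ir: float
    simulated_points: DoseResponseData
    simulated_fit: LL4Fit
    observed_fit: LL4Fit
    distance: float
    sign: int
    per_dose_delta: dict[float, float]

    @property
    def signed_score(self) -> float:
        return self.sign * self.distance


def ir_impulse(p_ir_ctrl: float, p_ni_ctrl: float) -> float:
    """Conditional kill of irradiation beyond baseline mortality.

    ``q = (p_ir_ctrl - p_ni_ctrl) / (1 - p_ni_ctrl)`` — the probability
    that irradiation kills a cell that baseline conditions spared.
    """
    if not (0.0 <= p_ni_ctrl < 1.0):
        raise ValueError(f"p_ni_ctrl must be in [0, 1), got {p_ni_ctrl}")
    if p_ir_ctrl < p_ni_ctrl:
        raise ValueError(
            "irradiated control mortality below non-irradiated control: "
            "protective irradiation is not modelled"
        )
    if p_ir_ctrl > 1.0:
        raise ValueError("p_ir_ctrl must be <= 1")
    return (p_ir_ctrl - p_ni_ctrl) / (1.0 - p_ni_ctrl)


def transfer_impulse(p_ni: float, q: float):
    """Independent-action combination ``1 - (1 - p_ni)(1 - q)``.

    Accepts scalars or arrays; commutative, associative and monotone
    non-decreasing in both arguments, bounded in [0, 1].
    """
    p = np.asarray(p_ni, dtype=float)
    qq = np.asarray(q, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any((qq < 0) | (qq > 1)):
        raise ValueError("mortality fractions must be in [0, 1]")
    out = 1.0 - (1.0 - p) * (1.0 - qq)
    if np.ndim(p_ni) == 0 and np.ndim(q) == 0:
        return float(out)
    return out


def simulate_ir_curve(ni_data: DoseResponseData, q: float) -> DoseResponseData:
    """Map every non-irradiated mortality through the IR impulse."""
    sim = transfer_impulse(ni_data.responses, q)
    return DoseResponseData(
        doses=ni_data.doses.copy(),
        responses=np.atleast_1d(sim),
        replicate_ids=None if ni_data.replicate_ids is None else ni_data.replicate_ids.copy(),
    )


def _coef_vector(p: LL4Params) -> np.ndarray:
    return np.array([p.lower, p.upper, np.log(p.ed50), p.shape])


def coefficient_distance(
    p_sim: LL4Params,
    p_obs: LL4Params,
    scaling: np.ndarray | str = "unit",
) -> float:
    """Euclidean distance between LL4 coefficient vectors.

    Coordinates are ``(lower, upper, ln ed50, shape)``.  ``scaling`` is
    either ``"unit"`` (raw differences) or an array of four positive
    scale factors (e.g. bootstrap standard errors) dividing each
    coordinate difference.
    """
    v1, v2 = _coef_vector(p_sim), _coef_vector(p_obs)
    if isinstance(scaling, str):
        if scaling != "unit":
            raise ValueError(f"unknown scaling {scaling!r}")
        scale = np.ones(4)
    else:
        scale = np.asarray(scaling, dtype=float)
        if scale.shape != (4,) or np.any(scale <= 0):
            raise ValueError("scaling must be four positive factors")
    return float(np.linalg.norm((v1 - v2) / scale))


def synergy_call(
    obs: DoseResponseData,
    ni: DoseResponseData,
    controls: tuple[float, float],
    scaling: np.ndarray | str = "unit",
    sign_tolerance: float = SIGN_TOLERANCE,
    fit_seed: int = 0,
) -> SynergyResult:
    """Full synergy assessment for one nanomaterial and timepoint.

    Parameters
    ----------
    obs : observed irradiated dose-response (mortality fractions).
    ni : non-irradiated dose-response on the same dose grid.
    controls : (p_ni_ctrl, p_ir_ctrl) dose-0 mortalities used for the
        IR impulse.
    """
    obs_doses = np.unique(obs.doses)
    ni_doses = np.unique(ni.doses)
    if not np.array_equal(obs_doses, ni_doses):
        raise ValueError("observed and non-irradiated dose grids must match")

    p_ni_ctrl, p_ir_ctrl = controls
    q = ir_impulse(p_ir_ctrl, p_ni_ctrl)
    simulated = simulate_ir_curve(ni, q)
    sim_fit = fit_ll4(simulated, seed=fit_seed)
    obs_fit = fit_ll4(obs, seed=fit_seed)
    dist = coefficient_distance(sim_fit.params, obs_fit.params, scaling=scaling)

    # per-dose mean observed minus simulated mortality
    deltas: dict[float, float] = {}
    for d in obs_doses:
        o = float(np.mean(obs.responses[obs.doses == d]))
        s = float(np.mean(simulated.responses[simulated.doses == d]))
        deltas[float(d)] = o - s
    nonzero = [v for d, v in deltas.items() if d > 0]
    mean_delta = float(np.mean(nonzero)) if nonzero else 0.0
    if abs(mean_delta) <= sign_tolerance:
        sign = 0
    else:
        sign = 1 if mean_delta > 0 else -1

    return SynergyResult(
        q_ir=q, simulated_points=simulated, simulated_fit=sim_fit,
        observed_fit=obs_fit, distance=dist, sign=sign, per_dose_delta=deltas,
    )


def synergy_heatmap(
    results: dict[tuple[str, float], SynergyResult],
) -> pd.DataFrame:
    """Signed-score matrix (rows: NM type, columns: timepoint, hours).

    Each cell is ``sign * distance``; missing cells are NaN.
    """
    if not results:
        raise ValueError("need at least one synergy result")
    nms = sorted({k[0] for k in results})
    times = sorted({k[1] for k in results})
    mat = pd.DataFrame(np.nan, index=nms, columns=times)
    for (nm, t), res in results.items():
        mat.loc[nm, t] = res.signed_score
    mat.index.name = "nm_type"
    mat.columns.name = "timepoint_h"
    return mat


def null_distance_tolerance(
    null_distances: np.ndarray, percentile: float = 95.0
) -> float:
    """Calibrated "distance ~ 0" cutoff: a percentile of null replicates."""
    arr = np.asarray(null_distances, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least two null replicates")
    return float(np.percentile(arr, percentile))
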