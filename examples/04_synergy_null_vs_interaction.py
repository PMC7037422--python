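"""Synergy scoring: a null world versus a world with a true interaction.

Two synthetic experiments are scored. In the first the combined
mortality follows independent action exactly (synergy_coeff = 0); in the
second an interaction term adds extra killing when nanomaterial and
irradiation co-occur. The signed coefficient distance separates them.
"""

import numpy as np

from radsynergy import DoseResponseData, NMType, synergy_call
from radsynergy.conditions import DOSE_GRID
from radsynergy.synthdata import default_generative_params, simulate_death_dataset


def score_world(synergy_coeff: float, seed: int):
    gp = default_generative_params(NMType.TIO2, 72.0, synergy_coeff)
    df = simulate_death_dataset(gp, DOSE_GRID, n_events=10_000,
                                n_replicates=3, seed=seed)
    ni, ir = df[~df.irradiated], df[df.irradiated]
    return synergy_call(
        DoseResponseData(ir.dose_surface.to_numpy(), ir.mortality.to_numpy()),
        DoseResponseData(ni.dose_surface.to_numpy(), ni.mortality.to_numpy()),
        (float(ni[ni.dose_surface == 0].mortality.mean()),
         float(ir[ir.dose_surface == 0].mortality.mean())),
    )


for label, syn in (("null world (independent action)", 0.0),
                   ("interaction world (synergy_coeff 0.8)", 0.8)):
    res = score_world(syn, seed=42)
    top = max(d for d in res.per_dose_delta if d > 0)
    print(f"{label}:")
    print(f"  IR impulse q        : {res.q_ir:.3f}")
    print(f"  coefficient distance: {res.distance:.3f}")
    print(f"  sign                : {res.sign:+d}")
    print(f"  signed score        : {res.signed_score:+.3f}")
    print(f"  delta at top dose   : {res.per_dose_delta[top]:+.3f}\n")
# The null world gets sign 0 (signed score 0): its per-dose deltas are
# pure noise, and the raw coefficient distance between two fits of the
# same noisy curve is itself noisy — which is why the calibrated cutoff
# comes from null replicates, not from a single number. The interaction
# world is called +1, with a ~10-point mortality excess at the top dose.
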