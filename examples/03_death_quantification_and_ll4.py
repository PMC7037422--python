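"""From raw events to an LL4 mortality curve.

Simulated cytometry samples are classified into live / apoptotic / dead
quadrants (DiOC6 vs PI), and the resulting mortality-vs-dose points are
fitted with the four-parameter log-logistic model.
"""

import numpy as np

from radsynergy import (
    DoseResponseData,
    NMType,
    SampleCondition,
    classify_death,
    default_generative_params,
    derive_fluor_thresholds,
    fit_ll4,
    simulate_events,
)

gp = default_generative_params(NMType.TIO2, timepoint_h=72.0)
doses = [0.0, 6.0, 16.0, 32.0, 48.0, 64.0]

# gates from a pooled sample so both live and dead modes are present
pool = simulate_events(
    SampleCondition(NMType.TIO2, 48.0, True, timepoint_h=72.0), gp, 30_000, seed=0
)
thr = derive_fluor_thresholds(pool)
print(f"DiOC gate {thr.dioc:.0f} a.u., PI gate {thr.pi:.0f} a.u. ({thr.provenance})\n")

print(f"{'dose':>6} {'live':>7} {'apopt':>7} {'dead':>7} {'mortality':>10}")
mortality = []
for d in doses:
    nm = NMType.TIO2 if d else NMType.NONE
    s = simulate_events(SampleCondition(nm, d, False, timepoint_h=72.0),
                        gp, 20_000, seed=int(d) + 100)
    f = classify_death(s, thr.dioc, thr.pi)
    mortality.append(f.mortality)
    print(f"{d:>6.0f} {f.live:>7.3f} {f.apoptotic:>7.3f} {f.dead:>7.3f} "
          f"{f.mortality:>10.3f}")

fit = fit_ll4(DoseResponseData(np.array(doses), np.array(mortality)), seed=0)
p = fit.params
print(f"\nLL4 fit: lower={p.lower:.3f} upper={p.upper:.3f} "
      f"ed50={p.ed50:.1f} ug/cm2 shape={p.shape:.2f} (SSE {fit.sse:.2e})")
print(f"generator truth: lower={gp.nm_ll4.lower} upper={gp.nm_ll4.upper} "
      f"ed50={gp.nm_ll4.ed50} shape={gp.nm_ll4.shape}")
# The baseline and the curve over the sampled range are recovered well
# (tiny SSE); the upper asymptote and ed50 are only weakly identified
# because the dose grid ends below the half-effect dose — exactly the
# regime where coefficient comparisons need a calibrated null.
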