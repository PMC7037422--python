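"""Automated nucleus counting and growth inhibition.

Simulated Hoechst-like fields are counted (smooth -> Otsu -> 8-connected
components) and turned into a growth series; treatment slows growth via
its mortality, quantified as fractional inhibition versus control.
"""

from radsynergy import (
    NMType,
    SampleCondition,
    build_growth_series,
    growth_inhibition,
    simulate_growth_images,
)
from radsynergy.synthdata import default_generative_params

gp = default_generative_params(NMType.TIO2, timepoint_h=72.0)
days = [0, 1, 2, 3]


def series_for(dose: float):
    nm = NMType.TIO2 if dose else NMType.NONE
    cond = SampleCondition(nm, dose, False)
    images = {d: simulate_growth_images(cond, d, gp, n_fields=5, seed=7)
              for d in days}
    return build_growth_series(images)


control = series_for(0.0)
treated = series_for(48.0)

print(f"{'day':>4} {'control':>9} {'48 ug/cm2':>10}")
for d in days:
    print(f"{d:>4} {control.mean_at(d):>9.1f} {treated.mean_at(d):>10.1f}")

inh = growth_inhibition(treated, control, day=days[-1])
print(f"\ngrowth inhibition at day {days[-1]}: {100 * inh:.1f}%")
# Counts are exact on these zero-overlap fields (checked against the
# generator's ground truth), so the inhibition reflects the mortality
# the generator imposed, not counting error.
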