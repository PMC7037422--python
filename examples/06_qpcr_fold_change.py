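"""Oxidative-stress readout: HMOX1 fold change by 2^-ddCt.

Simulated Ct tables are converted to fold changes relative to the
untreated non-irradiated control. HMOX1 responds to the dose- and
irradiation-dependent stress score; the defence genes NQO1 and TXNRD1
stay flat in this world.
"""

import pandas as pd

from radsynergy import NMType, SampleCondition, fold_changes, simulate_pcr
from radsynergy.synthdata import default_generative_params

gp = default_generative_params(NMType.TIO2, timepoint_h=24.0)

tables = []
for irradiated in (False, True):
    for dose in (0.0, 16.0, 32.0):
        cond = SampleCondition(NMType.TIO2 if dose else NMType.NONE, dose,
                               irradiated, timepoint_h=24.0)
        tables.append(simulate_pcr(cond, gp, seed=int(dose) + 50 * irradiated))
ct = pd.concat(tables, ignore_index=True)

fc = fold_changes(ct.drop(columns="nm_type"), reference_gene="GAPDH")
pivot = fc.pivot_table(index=["dose_surface", "irradiated"], columns="gene",
                       values="fold_change").round(2)
print(pivot)
# HMOX1 rises with dose and further with irradiation (the control row is
# 1 by construction); NQO1/TXNRD1 hover near 1 — no defence-gene induction.
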