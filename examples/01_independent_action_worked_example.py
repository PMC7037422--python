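"""Worked example: is the combined NM + 4 Gy mortality more than independent action?

Inputs are the single-agent mortalities reported for uncoated TiO2 at
64 µg/cm² (27.95% at 72 h) and for the 4 Gy irradiated control (25.5%).
The independent-action (Bliss) null predicts the combined mortality if
the two insults kill independently; an observed value above it indicates
radiosensitization.
"""

from radsynergy import ir_impulse, transfer_impulse

p_nm = 0.2795       # nanomaterial alone, 64 ug/cm2, 72 h
p_ir_ctrl = 0.255   # 4 Gy alone (no-NM control), 72 h
observed = 0.47     # combined exposure, measured

q = ir_impulse(p_ir_ctrl, 0.0)          # conditional kill of irradiation
predicted = transfer_impulse(p_nm, q)   # independent-action combination

print(f"IR impulse q                  : {q:.4f}")
print(f"predicted combined mortality  : {100 * predicted:.2f}%")
print(f"observed combined mortality   : {100 * observed:.2f}%")
print(f"excess over independent action: {100 * (observed - predicted):.2f} points")
# The observed 47% exceeds the 46.32% null prediction: the nanomaterial
# kills more under irradiation than two independent insults would.
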