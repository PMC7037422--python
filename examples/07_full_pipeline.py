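"""One-command end-to-end run: generate -> gate -> death -> fit -> synergy
-> growth -> pcr -> report.

Equivalent CLI: radsynergy run --config cfg.yaml --outdir scratch/demo
"""

from radsynergy import run_pipeline, validate_config

cfg = validate_config({
    "nm_types": ["TiO2"],
    "timepoints_h": [72.0],
    "n_events": 4000,
    "n_replicates": 3,
    "synergy_coeff": 0.8,     # a world with a real interaction
    "seed": 1,
    "outdir": "scratch/demo_run",
    "growth": {"days": [0, 1, 2], "n_fields": 3},
})

report = run_pipeline(cfg)
print("outputs:")
for name, path in report.outputs.items():
    print(f"  {name:>15}: {path}")
print("\nsynergy heatmap (sign x coefficient distance):")
print(report.heatmap.round(3))
print(f"\nsummary: {report.summary}")
print(f"provenance hash: {report.provenance_hash[:16]}...")
# A positive heatmap entry says the observed irradiated curve diverges
# from the independent-action null in the direction of extra killing.
# Re-running with the same config reproduces the hash bit-for-bit.
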