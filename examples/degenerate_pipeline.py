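"""Walk the whole pipeline on a hand-countable scenario.

100 TAVR implants in 2000; every valve fails after exactly 5 years, every
patient survives exactly 10, penetration is 100% and there are no redo
surgeries — so all 100 patients must return as TAVR-in-TAVR in 2005.
"""

import vivforecast as vf

cfg = vf.degenerate_config(
    tavr_cohorts={2000: 100},
    tavr_durability=5.0,
    survival_intermediate_high=10.0,
    penetration_tavr=1.0,
)
forecast = vf.run_single_replicate(cfg, replicate_seed=0)
print(forecast.to_frame().to_string(index=False))
print()
print("All 100 patients fail in 2005 (index 2000 + floor(5.0)) and are treated.")

# flip survival below durability: valves outlive their patients, no ViV at all
cfg = vf.degenerate_config(
    tavr_cohorts={2000: 100},
    tavr_durability=5.0,
    survival_intermediate_high=3.0,
)
forecast = vf.run_single_replicate(cfg, replicate_seed=0)
print(f"\nWith survival (3y) below durability (5y): total ViV = "
      f"{int(forecast.total_viv.sum())} — every patient dies before valve failure.")
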