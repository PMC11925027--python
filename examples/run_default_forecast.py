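"""Run the packaged US valve-in-valve forecast and print its headline numbers.

Uses a 5-replicate ensemble to keep the demo quick (the packaged default is
20); each replicate simulates ~4.4 million patients seeded from the annual
TAVR and bioprosthetic-SAVR volume series, 1998-2035.
"""

import vivforecast as vf

cfg = vf.default_config()
cfg.n_replicates = 5

summary = vf.run_ensemble(cfg)
headline = vf.compute_headline(summary, cfg.tavr_volumes)

print(f"ensemble: {summary.n_replicates} replicates, seed {summary.master_seed}")
print(f"total ViV in 2035:       {headline.total_viv_end:,.0f} procedures "
      f"(ensemble mean; SD {headline.sd_total[2035]:.0f})")
print(f"ViV share of all TAVR:   {100 * headline.viv_share_end:.1f}% in 2035")
print(f"TAVR-in-TAVR reaches 0.9x TAVR-in-SAVR in {headline.crossover_year_near}, "
      f"passes it in {headline.crossover_year_strict}")
print()
print("year  TAVR-in-SAVR  TAVR-in-TAVR   total ViV")
for year in (2020, 2025, 2030, 2035):
    i = list(summary.years).index(year)
    print(f"{year}  {summary.tavr_in_savr_mean[i]:12,.0f}  "
          f"{summary.tavr_in_tavr_mean[i]:12,.0f}  {summary.total_mean[i]:10,.0f}")
print()
print("TAVR-in-SAVR plateaus while TAVR-in-TAVR grows with the ageing TAVR")
print("population, so the total ViV curve is increasingly TAVR-in-TAVR.")
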