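# Default adult vaping exposure scenario.
# Physiology follows the EPA default adult (70 kg body weight, 20 m3/day
# breathing volume, 70-year exposure duration averaged over 70*365 days),
# behaviour follows survey data (163 puffs/day) and a leakage assumption of
# 0.05 ml/day chronic e-liquid contact for both the oral and dermal routes.
bw: 70            # body weight, kg
t_puffs: 163      # puffs per day
breathing_volume: 20   # m3/day, used only to convert air-concentration thresholds to doses
ci: 0.05          # chronic e-liquid contact volume, ml/day (oral and dermal)
ai: 10            # acute e-liquid intake, ml (one accidental-ingestion event)
ef: 365           # exposure frequency, days/year
ed: 70            # exposure duration, years
at: 25550         # averaging time, days (= 70 * 365)
sa: 5700          # exposed skin area, cm2
af: 0.2           # skin adherence factor, mg/(cm2 day)
cf: 1             # unit conversion factor (canonical units already consistent)
abs_default: 0.001     # dermal absorption fraction for chemicals not listed below
abs_by_chemical:
  As: 0.03
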