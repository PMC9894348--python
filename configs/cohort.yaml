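# Cohort-assembly configuration (defaults shown; substitute curated code
# sets for a real deployment).  Load with CohortConfig.from_yaml().
engagement_window: [2017-07-01, 2020-06-30]
anchor_date: 2020-07-01
hba1c_lookback_years: 2
hba1c_threshold: 6.5
dm_code_prefixes: [E10, E11, "250"]
dm_exclusion_code_prefixes: [O24, "648.8", R73, E09, "249"]
aud_code_prefixes: [F10, "303", "305.0"]
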