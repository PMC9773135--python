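# Model inputs for first-line sintilimab + chemotherapy (SIDCHM) versus
# placebo + chemotherapy (PLCHM) in advanced/metastatic ESCC, Chinese
# healthcare-system perspective. Costs in 2021 USD (1 USD = 6.45 RMB).
settings:
  cycle_days: 21
  wtp: 37653.0
  death_horizon_threshold: 0.99
  max_cycles: 160
  sintilimab_max_cycles: 35      # 24-month cap expressed in 21-day cycles
  chemo_max_cycles: 6
  half_cycle_correction: false
  background_mortality_annual: 0.007
  vial_rounding: false
  tests_in_pd: true
  followup_in_pd: true

survival:   # S(t) = exp(-scale * t^shape), t in 21-day cycles
  sidchm_pfs: {scale: 0.039683, shape: 1.101677}
  sidchm_os:  {scale: 0.010568, shape: 1.284650}
  plchm_pfs:  {scale: 0.031633, shape: 1.437746}
  plchm_os:   {scale: 0.010993, shape: 1.4354050}

parameters:
  # Grade >=3 adverse-event incidences (per arm, once at model entry)
  ae_inc_sidchm_anemia:                     {base: 0.125, low: 0.100, high: 0.150, dist: beta,  units: probability}
  ae_inc_sidchm_leukopenia:                 {base: 0.174, low: 0.139, high: 0.209, dist: beta,  units: probability}
  ae_inc_sidchm_nausea_vomiting:            {base: 0.043, low: 0.034, high: 0.052, dist: beta,  units: probability}
  ae_inc_sidchm_neutropenia:                {base: 0.300, low: 0.240, high: 0.360, dist: beta,  units: probability}
  ae_inc_sidchm_asthenia_decreased_appetite: {base: 0.040, low: 0.032, high: 0.048, dist: beta, units: probability}
  ae_inc_sidchm_thrombocytopenia:           {base: 0.028, low: 0.022, high: 0.034, dist: beta,  units: probability}
  ae_inc_sidchm_febrile_neutropenia:        {base: 0.024, low: 0.019, high: 0.029, dist: beta,  units: probability}
  ae_inc_plchm_anemia:                      {base: 0.102, low: 0.082, high: 0.122, dist: beta,  units: probability}
  ae_inc_plchm_leukopenia:                  {base: 0.223, low: 0.178, high: 0.268, dist: beta,  units: probability}
  ae_inc_plchm_nausea_vomiting:             {base: 0.033, low: 0.026, high: 0.040, dist: beta,  units: probability}
  ae_inc_plchm_neutropenia:                 {base: 0.337, low: 0.270, high: 0.404, dist: beta,  units: probability}
  ae_inc_plchm_asthenia_decreased_appetite: {base: 0.045, low: 0.036, high: 0.054, dist: beta,  units: probability}
  ae_inc_plchm_thrombocytopenia:            {base: 0.030, low: 0.024, high: 0.036, dist: beta,  units: probability}
  ae_inc_plchm_febrile_neutropenia:         {base: 0.018, low: 0.014, high: 0.022, dist: beta,  units: probability}
  # Per-event management cost of each adverse event (shared between arms)
  ae_cost_anemia:                     {base: 510.23,  low: 408.18,  high: 612.28,  dist: gamma, units: USD}
  ae_cost_leukopenia:                 {base: 467.86,  low: 374.29,  high: 561.43,  dist: gamma, units: USD}
  ae_cost_nausea_vomiting:            {base: 49.42,   low: 39.54,   high: 59.30,   dist: gamma, units: USD}
  ae_cost_neutropenia:                {base: 84.21,   low: 67.37,   high: 101.05,  dist: gamma, units: USD}
  ae_cost_asthenia_decreased_appetite: {base: 126.84, low: 101.47,  high: 152.21,  dist: gamma, units: USD}
  ae_cost_thrombocytopenia:           {base: 1058.22, low: 846.58,  high: 1269.86, dist: gamma, units: USD}
  ae_cost_febrile_neutropenia:        {base: 997.41,  low: 797.93,  high: 1196.89, dist: gamma, units: USD}
  # Drug acquisition prices, national tender, per 100 mg
  price_paclitaxel:   {base: 117.83, low: 94.26,  high: 141.40, dist: gamma, units: USD/100mg}
  price_cisplatin:    {base: 11.63,  low: 9.30,   high: 13.96,  dist: gamma, units: USD/100mg}
  price_fluorouracil: {base: 1.86,   low: 1.49,   high: 2.23,   dist: gamma, units: USD/100mg}
  price_sintilimab:   {base: 167.44, low: 133.95, high: 200.93, dist: gamma, units: USD/100mg}
  # Care costs
  cost_followup_per_cycle: {base: 73.86,   low: 59.09,   high: 88.64,   dist: gamma, units: USD/cycle}
  cost_tests:              {base: 358.03,  low: 286.42,  high: 429.63,  dist: gamma, units: USD/cycle}
  cost_end_of_life:        {base: 1831.90, low: 1465.52, high: 2198.28, dist: gamma, units: USD}
  cost_bsc:                {base: 167.96,  low: 134.37,  high: 201.55,  dist: gamma, units: USD/cycle}
  # Health-state utilities
  utility_pfs: {base: 0.68, low: 0.54, high: 0.82, dist: beta, units: utility}
  utility_pd:  {base: 0.42, low: 0.34, high: 0.50, dist: beta, units: utility}
  # Chemotherapy regimen mix (printed high of 1.12 is clamped to 1.0 on load)
  prop_paclitaxel:   {base: 0.93, low: 0.74,  high: 1.12,  dist: beta, units: proportion}
  prop_fluorouracil: {base: 0.07, low: 0.056, high: 0.084, dist: beta, units: proportion}
  # Other
  bsa:           {base: 1.72, low: 1.38, high: 2.06, dist: normal, units: m^2}
  discount_rate: {base: 0.03, low: 0.0,  high: 0.05, dist: fixed,  units: per-year}
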