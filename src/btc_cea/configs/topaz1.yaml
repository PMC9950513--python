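# First-line advanced biliary tract cancer: durvalumab + gemcitabine/cisplatin
# vs gemcitabine/cisplatin.  Base-case inputs for the US and Chinese payer
# perspectives with one-way sensitivity ranges and PSA distribution classes.
# Currency: 2021 USD.  Time unit for survival models: months.

settings:
  cycle_days: 21
  horizon_years: 10
  discount_cost: 0.03      # costs discounted at 3% per year
  discount_effect: 0.05    # LY/QALY discounted at 5% per year
  half_cycle: true
  transition_method: pd_exit
  weight_kg: 60

survival:                  # fixed in the model; excluded from OWSA/PSA
  durva:
    os:  {family: loglogistic, params: [1.81, 13.55]}   # shape, scale (months)
    pfs: {family: loglogistic, params: [2.19, 7.07]}
  chemo:
    os:  {family: loglogistic, params: [2.22, 11.68]}
    pfs: {family: gamma, params: [2.76, 0.38]}          # shape, rate (per month)

utilities:
  pfs: {value: 0.76, low: 0.61, high: 0.91, dist: beta}
  pd:  {value: 0.68, low: 0.54, high: 0.82, dist: beta}
  ae_duration_years: 1.0   # one-time AE disutility assumed to last one year

disutilities:
  leukopenia:       {value: -0.09,  low: -0.108, high: -0.072, dist: beta}
  anemia:           {value: -0.125, low: -0.150, high: -0.100, dist: beta}
  neutropenia:      {value: -0.09,  low: -0.108, high: -0.072, dist: beta}
  thrombocytopenia: {value: -0.20,  low: -0.240, high: -0.160, dist: beta}

ae:
  risks:               # grade >= 3 adverse events, per arm
    durva:
      neutrophil_count_decreased: {value: 0.207, low: 0.1656, high: 0.2484, dist: beta}
      neutropenia:                {value: 0.192, low: 0.1536, high: 0.2304, dist: beta}
      anemia:                     {value: 0.189, low: 0.1512, high: 0.2268, dist: beta}
      platelet_count_decreased:   {value: 0.08,  low: 0.064,  high: 0.096,  dist: beta}
    chemo:
      neutrophil_count_decreased: {value: 0.254, low: 0.2032, high: 0.3048, dist: beta}
      neutropenia:                {value: 0.202, low: 0.1616, high: 0.2424, dist: beta}
      anemia:                     {value: 0.187, low: 0.1496, high: 0.2244, dist: beta}
      platelet_count_decreased:   {value: 0.076, low: 0.0608, high: 0.0912, dist: beta}
  costs:               # one-time management cost per event, $
    neutrophil_count_decreased: {value: 466,  low: 373,  high: 559,  dist: gamma}
    anemia:                     {value: 531,  low: 425,  high: 638,  dist: gamma}
    neutropenia:                {value: 354,  low: 283,  high: 425,  dist: gamma}
    platelet_count_decreased:   {value: 1814, low: 1451, high: 2177, dist: gamma}

costs:
  us:
    drugs:             # $ per 21-day cycle
      gemcitabine:      {value: 15.06,  low: 12.04,    high: 18.07,    dist: gamma}
      cisplatin:        {value: 8.72,   low: 6.97,     high: 10.46,    dist: gamma}
      durvalumab:       {value: 11730,  low: 9384,     high: 14076,    dist: gamma}
      oxaliplatin:      {value: 26.76,  low: 21.41,    high: 32.11,    dist: gamma}
      calcium_folinate: {value: 52.48,  low: 41.98,    high: 62.97,    dist: gamma}
      fluorouracil:     {value: 18.57,  low: 14.86,    high: 22.29,    dist: gamma}
      irinotecan:       {value: 35.88,  low: 28.70,    high: 43.05,    dist: gamma}
      capecitabine:     {value: 180.6,  low: 144.48,   high: 216.72,   dist: gamma}
      regorafenib:      {value: 21546,  low: 17236.8,  high: 25855.2,  dist: gamma}
  china:
    drugs:
      gemcitabine:      {value: 5.92,     low: 4.74,    high: 7.11,     dist: gamma}
      cisplatin:        {value: 4.96,     low: 3.96,    high: 5.95,     dist: gamma}
      durvalumab:       {value: 11225.18, low: 8980.15, high: 13470.22, dist: gamma}
      oxaliplatin:      {value: 112.14,   low: 89.71,   high: 134.57,   dist: gamma}
      calcium_folinate: {value: 22.24,    low: 17.79,   high: 26.69,    dist: gamma}
      fluorouracil:     {value: 140.97,   low: 112.77,  high: 169.16,   dist: gamma}
      irinotecan:       {value: 547.28,   low: 437.83,  high: 656.74,   dist: gamma}
      capecitabine:     {value: 43.2,     low: 11.94,   high: 99.73,    dist: gamma}
      regorafenib:      {value: 1495.21,  low: 1196.17, high: 1794.25,  dist: gamma}

followup:              # $ per cycle; applied under both perspectives
  lab_first:     {value: 482.07,  low: 45.60,   high: 662.13,  dist: gamma}
  lab_pfs:       {value: 266.00,  low: 91.96,   high: 446.06,  dist: gamma}
  lab_pd:        {value: 390.57,  low: 142.19,  high: 626.12,  dist: gamma}
  imaging_first: {value: 1457.11, low: 1221.95, high: 1832.77, dist: gamma}
  imaging_pfs:   {value: 246.91,  low: 11.75,   high: 622.57,  dist: gamma}
  imaging_pd:    {value: 466.62,  low: 246.83,  high: 1832.77, dist: gamma}
  bed:           {value: 349.12,  low: 49.46,   high: 1219.47, dist: gamma}
  care:          {value: 404.74,  low: 71.10,   high: 1030.49, dist: gamma}

subsequent_therapy:
  max_cycles: 6        # cycles of second-line drug cost per PD entrant
  proportions:
    durva:
      chemotherapy:  {value: 0.417, low: 0.334, high: 0.500, dist: beta}
      targeted:      {value: 0.035, low: 0.028, high: 0.042, dist: beta}
      immunotherapy: {value: 0.009, low: 0.007, high: 0.011, dist: beta}
      other:         {value: 0.044, low: 0.035, high: 0.053, dist: beta}
    chemo:
      chemotherapy:  {value: 0.479, low: 0.383, high: 0.575, dist: beta}
      targeted:      {value: 0.047, low: 0.038, high: 0.056, dist: beta}
      immunotherapy: {value: 0.047, low: 0.038, high: 0.056, dist: beta}
      other:         {value: 0.081, low: 0.065, high: 0.097, dist: beta}
  regimens:
    chemotherapy: [oxaliplatin, calcium_folinate, fluorouracil]   # FOLFOX
    targeted: [regorafenib]
    immunotherapy: [durvalumab]
    other: [irinotecan, capecitabine]

treatment:
  gp_max_cycles: 8            # gemcitabine/cisplatin: trial regimen length
  durvalumab_max_months: 36   # durvalumab: until progression, capped

wtp:                   # willingness to pay, $/QALY
  us: 150000
  china: 38334         # 3x 2021 GDP per capita
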