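# Economic inputs for the partitioned survival model (2019 US$).
# Each uncertain input carries: value (deterministic), dist (beta | gamma |
# normal | fixed), low, high.  Bounds are treated as a 95% interval when
# deriving distribution parameters for probabilistic sensitivity analysis.

patient:
  weight_kg: 70.0
  bsa_m2: 1.86
  crcl_ml_min: 70.0

cycle:
  length_days: 21
  horizon_years: 2.5

discount_rate:
  value: 0.03
  dist: fixed
  low: 0.0
  high: 0.05

utilities:
  pf: {value: 0.840, dist: beta, low: 0.672, high: 0.883}
  pp: {value: 0.473, dist: beta, low: 0.166, high: 0.568}

# unit_size is the package size the price refers to (mg); pricing is linear.
unit_costs:
  atezolizumab:     {unit_size: 10.0,  value: 77.46, dist: gamma, low: 77.01, high: 77.76}
  etoposide:        {unit_size: 10.0,  value: 0.66,  dist: gamma, low: 0.56,  high: 0.74}
  carboplatin:      {unit_size: 50.0,  value: 3.09,  dist: gamma, low: 2.89,  high: 3.25}
  topotecan:        {unit_size: 0.1,   value: 0.94,  dist: gamma, low: 0.87,  high: 1.01}
  cyclophosphamide: {unit_size: 100.0, value: 3.91,  dist: gamma, low: 3.31,  high: 4.54}
  doxorubicin:      {unit_size: 10.0,  value: 3.08,  dist: gamma, low: 2.89,  high: 3.73}
  vincristine:      {unit_size: 1.0,   value: 4.88,  dist: gamma, low: 4.79,  high: 5.00}

other_costs:
  supportive_care_per_cycle: {value: 478.0,  dist: gamma, low: 359.0,  high: 597.0}
  death:                     {value: 9433.0, dist: gamma, low: 7075.0, high: 11791.0}
  admin_first:               {value: 144.72, dist: gamma, low: 115.78, high: 173.66}
  admin_additional:          {value: 31.68,  dist: gamma, low: 25.34,  high: 38.02}

adverse_events:
  neutropenia:
    cost:       {value: 17181.0, dist: gamma, low: 13745.0, high: 20617.0}
    risk_intervention: {value: 0.23, dist: beta, low: 0.19, high: 0.28}
    risk_control:      {value: 0.25, dist: beta, low: 0.20, high: 0.29}
    disutility: {value: -0.09, dist: beta, low: -0.122, high: -0.062}
    duration_days: {value: 2.0, dist: normal, low: 2.0, high: 2.0}
  anemia:
    cost:       {value: 20260.0, dist: gamma, low: 16208.0, high: 24312.0}
    risk_intervention: {value: 0.14, dist: beta, low: 0.11, high: 0.17}
    risk_control:      {value: 0.12, dist: beta, low: 0.10, high: 0.15}
    disutility: {value: -0.09, dist: beta, low: -0.133, high: -0.055}
    duration_days: {value: 21.0, dist: normal, low: 17.0, high: 25.0}
  decreased_neutrophil_count:
    cost:       {value: 17181.0, dist: gamma, low: 13745.0, high: 20617.0}
    risk_intervention: {value: 0.14, dist: beta, low: 0.11, high: 0.17}
    risk_control:      {value: 0.17, dist: beta, low: 0.13, high: 0.20}
    disutility: {value: -0.09, dist: beta, low: -0.122, high: -0.062}
    duration_days: {value: 4.0, dist: normal, low: 3.0, high: 5.0}
  thrombocytopenia:
    cost:       {value: 22698.0, dist: gamma, low: 20289.0, high: 25377.0}
    risk_intervention: {value: 0.10, dist: beta, low: 0.08, high: 0.12}
    risk_control:      {value: 0.08, dist: beta, low: 0.06, high: 0.09}
    disutility: {value: -0.108, dist: beta, low: -0.128, high: -0.089}
    duration_days: {value: 24.0, dist: normal, low: 19.0, high: 28.0}
  leukopenia:
    cost:       {value: 17181.0, dist: gamma, low: 13745.0, high: 20617.0}
    risk_intervention: {value: 0.05, dist: beta, low: 0.04, high: 0.06}
    risk_control:      {value: 0.04, dist: beta, low: 0.03, high: 0.05}
    disutility: {value: -0.09, dist: beta, low: -0.122, high: -0.062}
    duration_days: {value: 2.0, dist: normal, low: 2.0, high: 2.0}

second_line:
  n_cycles: 4
  uptake_intervention:
    topotecan: {value: 0.403, dist: beta, low: 0.3224, high: 0.4836}
    cav:       {value: 0.154, dist: beta, low: 0.1232, high: 0.1848}
  uptake_control:
    topotecan: {value: 0.436, dist: beta, low: 0.3488, high: 0.5232}
    cav:       {value: 0.228, dist: beta, low: 0.1824, high: 0.2736}

regimen_settings:
  chemo_cycles: 4            # induction carboplatin + etoposide cycles
  etoposide_days_per_cycle: 3
  topotecan_days_per_cycle: 5
  carboplatin_auc: 5.0
  etoposide_mg_per_m2: 100.0
  topotecan_mg_per_m2: 1.5
  cyclophosphamide_mg_per_m2: 1000.0
  doxorubicin_mg_per_m2: 45.0
  vincristine_mg_flat: 2.0
  atezolizumab_mg_flat: 1200.0
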