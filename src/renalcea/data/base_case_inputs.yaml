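# Base-case inputs for the two-arm sequencing model: first-line
# nivolumab+cabozantinib versus sunitinib for advanced renal cell
# carcinoma, followed by axitinib, sorafenib and best supportive care.
# Costs are 2021 USD; survival scales are months.
settings:
  cycle_days: 42
  discount_rate_annual: 0.03
  wtp_per_qaly: 150000
  start_age: 62
  weight_kg: 70
  age_cap: 100
  half_cycle_correction: false

survival:
  pfs:
    nivolumab_cabozantinib: {family: loglogistic, shape: 1.569, scale: 15.064}
    sunitinib:              {family: loglogistic, shape: 1.646, scale: 8.269}
    axitinib:               {family: loglogistic, shape: 1.4633, scale: 6.6318}
    # single exponential parameter read as the mean survival time in months;
    # set parameterization: rate for the event-rate reading
    sorafenib:              {family: exponential, value: 2.281, parameterization: mean}
  bsc_os:                   {family: loglogistic, shape: 1.613, scale: 13.857}

probabilities:
  discontinuation_ae:   # cumulative over the line, due to adverse events
    nivolumab_cabozantinib: 0.197
    sunitinib: 0.169
    axitinib: 0.0849
    sorafenib: 0.1811
  ae_mortality:         # one-time treatment mortality due to adverse events
    nivolumab_cabozantinib: 0.0031
    sunitinib: 0.0061
    axitinib: 0.0
    sorafenib: 0.007
  ae_grade3plus:        # grade >=3 adverse events, weights the AE disutility
    nivolumab_cabozantinib: 0.753
    sunitinib: 0.706
    axitinib: 0.50
    sorafenib: 0.45

costs:
  unit_prices:
    nivolumab: 6849.84      # per 240 mg dose (3 doses per 42-day cycle)
    cabozantinib: 491.30    # per 60 mg unit; 40 mg daily, dose-proportional
    sunitinib: 623.08       # per 50 mg capsule; 28 of 42 days
    axitinib: 265.05        # per 5 mg unit; 2 units daily
    sorafenib: 174.00       # per 200 mg unit; 4 units daily
  admin_iv_infusion: 148.3  # per IV infusion (<= 1 h)
  bsc_per_cycle: 1256
  ae_management:            # one-time at line entry
    nivolumab_cabozantinib: 1214.68
    sunitinib: 6632.78
    axitinib: 4660.34
    sorafenib: 2284.81

utilities:
  first_line: 0.82
  second_line: 0.77
  third_line: 0.66
  bsc: 0.494
  ae_disutility: 0.157

life_table:
  gompertz: {B: 4.0266e-05, c: 1.094}

# one-way ranges as printed; unlisted costs/probabilities default to +/-20%
ranges:
  utility.first_line: [0.65, 0.98]
  utility.second_line: [0.616, 0.924]
  utility.third_line: [0.528, 0.792]
  utility.bsc: [0.403, 0.570]
  ae_disutility: [0.11, 0.204]
  weight_kg: [49.0, 93.8]
  start_age: [18, 75]

psa:
  sd:   # printed standard deviations; others derive from the range
    utility.second_line: 0.24
    utility.third_line: 0.30
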