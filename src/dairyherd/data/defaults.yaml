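# Packaged default parameters for the monthly dairy-herd replacement chain.
# Biological transition rates live in transition_rates.csv; the lactation
# curve in milk_curve.csv. Everything here can be overridden from a user
# parameter file (see dairyherd.params.load_params).

rates:
  # Monthly probability of abortion by month of gestation (detectable
  # abortions only; month 1 losses are not observable, month 9 is calving).
  abort_hazard:
    2: 0.035
    3: 0.025
    4: 0.015
    5: 0.005
    6: 0.0025
    7: 0.001
    8: 0.001
  # Split of detectable abortions (gestation month > 2) into rebreeding
  # abortions (cow keeps lactating, same parity) and new-lactation abortions
  # (cow starts a fresh lactation): NLA share = 1.9/12.5.
  nla_share: 0.152

effects:
  milk_reduction_ra: 0.073
  milk_reduction_nla: 0.194
  cull_risk_multiplier: 1.9

economics:
  milk_price: 0.36          # USD/kg
  calf_value: 100.0         # USD per calf born
  carcass_price: 1.16       # USD/kg body weight of a culled cow
  replacement_cost: 1300.0  # USD per replacement heifer
  vet_cost: 50.0            # USD, charged per calving by default
  vet_basis: per_calving    # per_calving | per_month
  feed_cost_lact: 0.17      # USD/kg DM while milking
  feed_cost_dry: 0.13       # USD/kg DM while dry
  dmi: 25.0                 # kg DM/day
  days_per_month: 30
  # The insemination price and cull-cow sale weight are not part of the
  # published price table; the packaged values are calibrated once against
  # the published sterile-herd net benefit (see docs/methods.md). A typical
  # commercial AI service runs 10-30 USD if charged separately.
  ai_cost: 0.0              # USD per insemination service
  carcass_weight: 563.0     # kg sale weight of a culled cow
  twin_loss: 0.0            # USD per calving lost to twin births
  dry_off_preg: 8           # gestation month at which milking stops
  max_milking_mil: 12       # lactation months a cow is milked at most
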