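# Calibration constraints distilled from the documented observations.
# Windows and deadlines in hours; margins and tolerances are fractions.
constraints:
  window: [12.0, 24.0]        # Scleraxis peak window under pressure+MGF
  return_deadline: 40.0       # back to baseline by this hour
  return_tol: 0.10            # "back": within 10% of pre-stimulus baseline
  ordering_margin: 0.10       # control < MGF < P+MGF, control < P < P+MGF
  pp2_margin: 0.20            # PP2 lowers P+MGF SCX window mean by >= 20%
  pp2_inhibition: 0.1
  include_pp2: true
  pattern_fak_tol: 0.10       # MGF alone: FAK_a within 10% of control
  kinase_up_margin: 0.05      # MGF raises Fyn/ERK, pressure raises all four
  include_pattern: true
  horizon: 48.0
  grid_step: 0.5
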