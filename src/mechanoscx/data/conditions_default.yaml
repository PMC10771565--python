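# Standard treatment conditions.
#
# mgf_initial: MGF ligand bolus (copies) added at t=0.
# pressure_segments: piecewise-constant envelope, [t_start h, t_end h, kPa].
# inhibition: Fyn activation scaling; 1 = untreated, 0.1 emulates 10 uM PP2.
conditions:
  - name: control
    mgf_initial: 0
    pressure_segments: []
    inhibition: 1.0
  - name: MGF
    mgf_initial: 100
    pressure_segments: []
    inhibition: 1.0
  - name: pressure
    mgf_initial: 0
    pressure_segments: [[0.0, 1.0, 120.0]]
    inhibition: 1.0
  - name: pressure+MGF
    mgf_initial: 100
    pressure_segments: [[0.0, 1.0, 120.0]]
    inhibition: 1.0
  - name: control+PP2
    mgf_initial: 0
    pressure_segments: []
    inhibition: 0.1
  - name: MGF+PP2
    mgf_initial: 100
    pressure_segments: []
    inhibition: 0.1
  - name: pressure+PP2
    mgf_initial: 0
    pressure_segments: [[0.0, 1.0, 120.0]]
    inhibition: 0.1
  - name: pressure+MGF+PP2
    mgf_initial: 100
    pressure_segments: [[0.0, 1.0, 120.0]]
    inhibition: 0.1
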