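# Bundled adult CBC reference panel.
# Units: neu/lym/plt 10^9/L, rbc 10^12/L, hb g/L.
# direction: which side of the mean carries death risk.
reference_panel:
  neu:
    mean: 3.5
    sd: 1.2
    direction: high_is_risk
  lym:
    mean: 2.2
    sd: 0.6
    direction: high_is_risk
  rbc:
    mean: 4.5
    sd: 0.6
    direction: low_is_risk
  hb:
    mean: 142.0
    sd: 20.0
    direction: low_is_risk
  plt:
    mean: 210.0
    sd: 53.0
    direction: low_is_risk
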