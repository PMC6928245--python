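# CPVT-phenotype cell under isoproterenol, 5 Hz burst protocol.
# Unspecified values take the package defaults (control calibration).
seed: 3
isoproterenol: true
cpvt:
  enabled: true
protocol:
  frequency: 5.0
  burst_time: 5.0
  observe_time: 15.0
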