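# mixed fast/slow responder on an annual timescale for `climdecomp scenarios`
temp_series:
  - [5.0, 4.6, 5.8, 5.2, 6.4, 5.0]
  - [7.0, 6.6, 7.8, 7.2, 8.4, 7.0]
  - [9.0, 8.6, 9.8, 9.2, 10.4, 9.0]
  - [11.0, 10.6, 11.8, 11.2, 12.4, 11.0]
response_type: mixed
delay: 1
slow_slope: -3.0
fast_slope: 2.0
baseline_abundance: 60.0
timescale: annual
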