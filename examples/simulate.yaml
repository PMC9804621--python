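# synthetic study region for `climdecomp simulate`
n_cells_x: 20
n_cells_y: 20
centering_years: [1971, 2018]
study_years: [1996, 2018]
n_routes: 150
scheme_start_year:
  "NO": 2006     # quote: bare NO is YAML for false (the "Norway problem")
  "SE": 1996
  "FI": 2006
seed: 20180531
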