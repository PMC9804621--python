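# small end-to-end synthetic run for `climdecomp run`
mode: synthetic
synthetic:
  n_cells_x: 10
  n_cells_y: 10
  n_routes: 60
  scheme_start_year: {"NO": 2008, "SE": 2004, "FI": 2008}
centering_years: [1996, 2015]
study_years: [2004, 2015]
family: nb
select_blocks: false
outdir: runs/example
seed: 7
log_level: WARNING
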