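# Bundled demonstration configuration: a 30-minute synthetic session run
# end-to-end (simulate -> score -> calcium -> photometry -> psp -> stim).
# Stimulation every 10 min keeps three trials inside the short session;
# experiment-scale runs use the 45-min default interval.
session:
  duration_min: 30
  seed: 42
simulate:
  n_cells: 10
  schedule_kind: fixed_interval
  schedule_interval_s: 600.0
  schedule_on_s: 120.0
  write_raw: true
stim:
  # wake-triggered stimulation, scaled to the 30-min demo session
  # (experiment-scale values: 300 s persistence, 1800 s between trials)
  trigger: closed_loop
  wake_persist_s: 60.0
  min_interval_s: 300.0
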