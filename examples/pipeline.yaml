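# Demo analysis configuration. Paths are resolved relative to this file.
population: data/population.csv
events: data/events.csv
conditions: data/conditions.csv
out_dir: out
study_start: 2000-01-01
study_end: 2015-12-31
lookback_start: 1995-01-01
privacy_threshold: 5
age_band_width: 5
age_band_open_from: 75
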