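# Data directory

- `survey_template.csv` — the required column layout for a surveyed-studies
  table (`study,n,accuracy,year,modality,classifier`). The three rows are
  fictional placeholders.
- `s1_studies.csv` (not shipped) — to reproduce the literature-survey numbers
  (Pearson r, Spearman rho, R², median N), transcribe the published
  supplementary studies table into this file using the template layout.
  `scripts/acceptance.py` and the survey acceptance test pick it up
  automatically when present. Synthetic stand-ins for testing are produced by
  `valbias.survey_analysis.make_survey_fixture`.
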