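# Demo pipeline config: expected-vs-observed comparison from the packaged
# published-inputs fixture plus a small checklist summary. No model constants
# are needed for this mode (richness and probabilities are fixture inputs).
seed: 1
outdir: invexpect_demo_run
exclude_phyla: [Tracheophyta]
inputs:
  table2: builtin:table2
  checklists:
    north_baltic: builtin:demo_north_baltic
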