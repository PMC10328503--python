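# Desk-scale demo of the full simulate -> process -> cluster -> stats run.
# All omitted keys take the study-mimicking defaults (see docs/methods.md).
out_dir: results/demo
seed: 0
simulate:
  n_library_molecules: 20000
  n_founders: 200
  copy_lambda: 3.0
  jackpot_prob: 0.05
  depth: 8000
  error_rate: 0.001
  duplicate_rate: 0.5
  n_integrants: 10000
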