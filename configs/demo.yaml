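# End-to-end demo: eight synthetic PDTX models (four pCR-like, four
# non-pCR-like), five mice per arm, weekly measurements for 11 weeks.
# Run with:  cotrial run-all --config configs/demo.yaml
seed: 1
out_dir: demo_run
n_pcr_models: 4
n_non_pcr_models: 4
n_mice_per_arm: 5
delta_pcr: -0.08
delta_non_pcr: -0.005
run_screen: true
run_variants: true
run_phenotype: true
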