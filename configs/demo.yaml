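# Demo pipeline configuration: full study design at reduced point count.
out_dir: results/demo
phases: [in_vivo, ex_vivo]
seed: 1
n_patients: 15
n_mixed: 13
n_healthy_only: 2
points_per_class: 600
interface_buffer_mm: 0.5
snr_min_db: 20.0
skew_threshold: 1.0
vif_threshold: 10.0
p_threshold: 0.05
classifier_family: tree
classifier_combo: auto
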