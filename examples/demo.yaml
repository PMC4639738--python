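# Demo run: synthetic study at reduced scan effort (fast).
# `scannet analyse --config examples/demo.yaml --out demo_out`
seed: 1
alpha: 0.05
min_class_n: 3
random_by: group
behaviours: [proximity, grooming_given]
synthetic:
  n_scans: 200
  periods: ["2003", "2005"]
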