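# Fast demonstration run: small synthetic cohort on a 20-region atlas.
out_dir: neurograph-demo
seed: 42
simulate: true
sim:
  n_ad: 8
  n_nc: 8
  T: 60
n_regions: 20
grid: "0.10:0.50:0.10"
alpha: 0.05
scores: [UPSIT]
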