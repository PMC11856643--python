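# Additive-world demo: item difficulties are weighted sums of the nine
# component base parameters (defaults: the published LLTM component
# estimates for the taxonomy).  Two independent samples of 600 examinees.
output_dir: scratch/additive_demo
simulation:
  model: additive
  seed: 20250901
  n_items: 18
  n_persons_fit: 600
  n_persons_cv: 600
  max_weight: 2
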