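# Conjunctive-world demo: solving an item requires mastering every component
# it involves; component mastery curves are steep logistic gates (defaults:
# discrimination 3, difficulties spread over [-2.5, 1]).
output_dir: scratch/conjunctive_demo
simulation:
  model: conjunctive
  seed: 20250902
  n_items: 18
  n_persons_fit: 600
  n_persons_cv: 600
  max_weight: 2
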