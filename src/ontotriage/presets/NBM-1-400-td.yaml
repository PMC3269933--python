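task: act
algorithm: nbm
selection_method: mi
orders: [1]
k: 400
training_split: train_plus_dev
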