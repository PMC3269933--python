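task: act
algorithm: svm_poly
selection_method: mi
orders: [1, 2]
k: 400
training_split: dev_only
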