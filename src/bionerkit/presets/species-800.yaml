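# Benchmark preset: species-800
max_length: 128
batch_size: 64
learning_rate: 5e-05
hidden_per_direction: 256
max_epochs: 100
validation_fraction: 0.10
patience: 10
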