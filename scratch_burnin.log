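seed 11 segregating 504
seed 12 segregating 493
seed 13 segregating 498
saved
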