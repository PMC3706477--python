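subset	positive	tested
overall	193	2430
predicted	90	795
unpredicted	103	1638
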