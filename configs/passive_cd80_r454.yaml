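version: 1
name: passive_cd80_r454
mode: passive
Cd: 80.0
r: 4.54
seed: 1
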