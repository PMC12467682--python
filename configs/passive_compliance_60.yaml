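version: 1
name: passive_compliance_60
mode: passive
Cd: 60.0
r: 3.14
seed: 1
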