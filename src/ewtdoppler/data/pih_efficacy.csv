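group,category,count,group_size
control,cured,106,250
control,markedly_effective,89,250
control,effective,31,250
control,ineffective,24,250
observation,cured,156,250
observation,markedly_effective,74,250
observation,effective,14,250
observation,ineffective,6,250
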