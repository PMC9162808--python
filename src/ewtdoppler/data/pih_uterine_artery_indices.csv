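group,index,mean,sd,n
control,RI,0.64,0.12,250
control,PI,1.26,0.35,250
control,SD_ratio,3.67,0.46,250
observation,RI,0.55,0.14,250
observation,PI,0.78,0.18,250
observation,SD_ratio,2.78,0.67,250
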