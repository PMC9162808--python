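group,category,count,group_size
control,cervical_laceration,8,250
control,fetal_distress,9,250
control,neonatal_asphyxia,11,250
control,postpartum_hemorrhage,15,250
control,reported_total,29,250
observation,cervical_laceration,3,250
observation,fetal_distress,2,250
observation,neonatal_asphyxia,4,250
observation,postpartum_hemorrhage,7,250
observation,reported_total,16,250
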