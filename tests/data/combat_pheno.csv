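site,group,age,gender
site1,patient,54.999,male
site1,control,25.956,male
site1,patient,40.343,male
site1,control,25.904,male
site1,patient,21.993,male
site1,control,23.157,male
site1,patient,27.704,male
site1,control,37.412,female
site1,patient,42.653,male
site1,control,33.238,male
site2,patient,39.324,male
site2,control,54.635,male
site2,patient,53.824,female
site2,control,26.358,female
site2,patient,43.721,female
site2,control,28.086,male
site2,patient,44.113,male
site2,control,41.394,male
site2,patient,28.582,female
site2,control,20.086,female
site3,patient,54.655,male
site3,control,54.853,male
site3,patient,51.23,female
site3,control,20.231,male
site3,patient,37.109,male
site3,control,34.587,male
site3,patient,22.708,female
site3,control,40.621,male
site3,patient,26.312,male
site3,control,53.27,female
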