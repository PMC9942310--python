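survey_id,raw_code,raw_label,canonical_label,category
*,extra,Extra,extra,extra
*,saving for later,Saving for later,saving for later,extra
*,stored away,Stored away,stored away,extra
*,saving to replace other net,Saving to replace other net,saving to replace other net,extra
*,chemicals not safe,Chemicals not safe,chemicals not safe,fears
*,net is bad for health,Net is bad for health,net is bad for health,fears
*,superstition/witchcraft,Superstition/witchcraft,superstition/witchcraft,fears
*,too rough/hard,Too rough/hard,too rough/hard,net_attributes
*,too small,Too small,too small,net_attributes
*,don't like colour/shape/size,Don't like colour/shape/size,don't like colour/shape/size,net_attributes
*,prefer other method,Prefer other method,prefer other method,net_attributes
*,too old/torn/dirty,Too old/torn/dirty,too old/torn/dirty,objective
*,no place to hang,No place to hang,no place to hang,objective
*,usual user didn't sleep here,Usual user didn't sleep here,usual user didn't sleep here,objective
*,usual user not here,Usual user not here,usual user didn't sleep here,objective
*,net being washed,Net being washed,net being washed,objective
*,too weak/difficult to hang,Too weak/difficult to hang,too weak/difficult to hang,objective
*,no mosquitoes,No mosquitoes,no mosquitoes,risk_perception
*,no/few mosquitoes,No/few mosquitoes,no mosquitoes,risk_perception
*,no malaria,No malaria,no malaria,risk_perception
*,saving for rainy season,Saving for rainy season,saving for rainy season,risk_perception
*,too hot,Too hot,too hot,subjective
*,don't like smell,Don't like smell,don't like smell,subjective
*,feel closed in/afraid,Feel closed in/afraid,feel closed in/afraid,subjective
*,no longer kills/repels mosquitoes,No longer kills/repels mosquitoes,no longer kills/repels mosquitoes,subjective
*,child doesn't like,Child doesn't like,child doesn't like,subjective
*,net never used,Net never used,net never used,subjective
*,causes itching/coughing,Causes itching/coughing,causes itching/coughing,subjective
*,brought bedbugs,Brought bedbugs,brought bedbugs,subjective
*,slept outdoors,Slept outdoors,slept outdoors,subjective
*,don't like net,Don't like net,don't like net,subjective
*,not needed last night,Not needed last night,not needed last night,other
*,not hung,Not hung,not hung,other
*,other,Other,other,other
*,don't know,Don't know,don't know,other
*,forgot,Forgot,forgot,other
*,missing,Missing,missing,other
*,unmapped,Unmapped,unmapped,other
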