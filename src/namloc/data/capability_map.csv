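hazard,pattern
methemoglobinemia,methemoglobin
methemoglobinemia,hemoglobin
cardiotoxicity,cardiac
cardiotoxicity,heart
cardiotoxicity,cardiomyocyte
cytotoxicity,cytotoxicity
cytotoxicity,cell death
cytotoxicity,viability
estrogenic_activity,oestrogen
estrogenic_activity,estrogen
estrogenic_activity,era_
estrogenic_activity,erb_
steroidogenesis,steroid hormone
proliferation,proliferation
thyroid_activity,thyroid
hepatotoxicity,liver
hepatotoxicity,heparg
neurotoxicity,neuro
neurotoxicity,brain
haemolytic_anaemia,erythrocyte
haemolytic_anaemia,hemolysis
splenotoxicity,spleen
endocrine_activity,nuclear receptor
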