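target_family,target_subfamily,biological_process,severity,note
Cell cycle,Proliferation,Cell death,H,cytotoxicity with cell death readout
Cell cycle,Cytotoxicity,*,H,cytotoxicity readouts
Cell cycle,Proliferation,Cell proliferation,H,proliferative responses
Nuclear receptor,Steroidal,Cell proliferation,H,steroid-receptor driven proliferation
Nuclear receptor,Steroidal - agonist,*,H,oestrogen/androgen receptor agonism; broad adverse-effect potential
Nuclear receptor,PPAR,*,L,peroxisome proliferator-activated receptor binding; disputed relevance
Steroid hormone,*,*,M,steroidogenesis modulation
Nuclear receptor,Non-steroidal,Protein stabilisation,M,non-steroidal receptor stabilisation
DNA binding,*,Regulation of transcription factor activity,M,transcription-factor modulation
Nuclear receptor,Steroidal,Regulation of transcription factor activity,L,receptor antagonist reporter readouts
Nuclear receptor,Orphan,*,L,orphan receptor readouts
Transferase,*,*,L,metabolic enzyme induction
Cyp,*,*,L,xenobiotic metabolism induction
Oxidoreductase,Peroxidase,*,L,catalytic-activity modulation
*,*,*,M,fallback: unknown descriptors are neither exculpatory nor damning
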