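drug_id,name,drug_class,known_nci_cotreatment
D01,anastrozole,AI,false
D02,letrozole,AI,false
D03,exemestane,AI,false
D04,tamoxifen,SERM,false
D05,toremifene,SERM,false
D06,fulvestrant,SERD,false
D07,palbociclib,iCDK46,false
D08,ribociclib,iCDK46,false
D09,abemaciclib,iCDK46,false
D10,capecitabine,antineoplastic,false
D11,paclitaxel,antineoplastic,false
D12,trastuzumab,antineoplastic,false
D13,pembrolizumab,immunotherapy,false
D14,atezolizumab,immunotherapy,false
D15,paracetamol,other,false
D16,omeprazole,other,false
D17,levothyroxine,other,false
D18,oxycodone,other,true
D19,zolpidem,other,true
D20,amlodipine,other,false
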