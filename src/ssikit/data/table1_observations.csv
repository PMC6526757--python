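patient_id,mi,artery,treated,pci_site_id
I,Y,RCA,1,I_RCA_lesion
I,Y,LAD,0,
I,Y,LCX,1,I_LCX_lesion
II,Y,RCA,0,
II,Y,LAD,1,II_LAD_lesion
II,Y,LCX,1,II_LCX_lesion
III,N,RCA,0,
III,N,LAD,0,
III,N,LCX,1,III_LCX_lesion
IV,N,RCA,1,IV_RCA_lesion
IV,N,LAD,0,
V,Y,RCA,0,
V,Y,LAD,1,V_LAD_pci
V,Y,LCX,0,
VI,Y,RCA,0,
VI,Y,LAD,1,VI_LAD_pci
VI,Y,LCX,0,
VII,N,RCA,1,VII_RCA_lesion
VII,N,LAD,0,
VII,N,LCX,0,
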