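metabolite,medium,concentration,units
folate,RPMI,1,mg/L
folate,DMEM,4,mg/L
aspartate,RPMI,150,uM
aspartate,DMEM,0,uM
glucose,RPMI,2000,mg/L
glucose,DMEM,4500,mg/L
glutamine,RPMI,300,mg/L
glutamine,DMEM,584,mg/L
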