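element,low,high,unit
As,20,72,mg/kg
Cd,1.5,10,mg/kg
Cu,65,270,mg/kg
Cr,80,370,mg/kg
Pb,50,220,mg/kg
Zn,200,200,mg/kg
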