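determinand,stream,value,spread,units
pH,influent,7.2,0.2,-
temperature,influent,23,2.0,C
COD,influent,440.4,25.7,mg/L
BOD,influent,221.6,18.4,mg/L
TSS,influent,262.9,27.6,mg/L
NH3,influent,34.5,9.6,mg/L
TKN,influent,42.5,9.6,mg/L
TN,influent,45.9,11.6,mg/L
COD,effluent,25.5,,mg/L
BOD,effluent,9.0,,mg/L
TSS,effluent,15.0,,mg/L
NH3,effluent,0.2,0.2,mg/L
TKN,effluent,1.3,,mg/L
TN,effluent,14.2,,mg/L
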