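determinand,stream,value,spread,units
pH,influent,7.0,0.6,-
temperature,influent,26,4,C
COD,influent,627,188,mg/L
BOD,influent,306,84,mg/L
TSS,influent,384,80,mg/L
NH3,influent,33.7,8.2,mg/L
TKN,influent,44.2,7.1,mg/L
TN,influent,46.7,8.5,mg/L
COD,effluent,62,5,mg/L
BOD,effluent,31,,mg/L
TSS,effluent,37,,mg/L
NH3,effluent,4.9,1.6,mg/L
TKN,effluent,6.2,,mg/L
TN,effluent,14.0,,mg/L
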