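determinand,stream,value,spread,units
pH,influent,7.2,0.2,-
temperature,influent,26.5,1.5,C
COD,influent,455.6,37.1,mg/L
BOD,influent,232.8,29.8,mg/L
TSS,influent,316.6,34.7,mg/L
NH3,influent,40.8,7.9,mg/L
TKN,influent,48.6,7.6,mg/L
TN,influent,50.7,8.6,mg/L
COD,effluent,85.0,,mg/L
BOD,effluent,46.0,,mg/L
TSS,effluent,58.0,,mg/L
NH3,effluent,32.8,14.3,mg/L
TKN,effluent,35.6,,mg/L
TN,effluent,43.6,,mg/L
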