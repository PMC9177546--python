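code,shape,low,high,center,source
X52,uniform,0.63,0.69,,literature consensus range for aerobic heterotrophic yield
X53,uniform,0.52,0.57,,literature consensus range for anoxic heterotrophic yield
X16,uniform,0.23,0.7,,span of reported aerobic heterotrophic decay rates
X12,uniform,0.375,0.48,,half of reported total denitrification reduction factors (equal NO2/NO3 split assumed)
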