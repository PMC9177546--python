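# Operational settings, high-oxygen validation regime (DO 4.5 mg/L)
volume_m3: 20.0
flow_m3h: 1.8
srt_d: 22.0
ras_ratio: 3.0
ras_flow_m3h: null
was_flow_m3d: 2.2
do_mg_l: 4.5
temperature_c: 23.0
mlss_mg_l: 2000.0
media_fill: 0.005
attached_capacity_gcod: 20000.0
biofilm_do_attenuation: 0.05
clarifier_f_ns: 0.005
f_bod: 0.66
cod_per_vss: 1.48
vss_per_tss: 0.63
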