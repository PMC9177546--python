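code,name,units,kind,default,low,high,pdf
X52,Aerobic heterotrophic yield on soluble substrate,mgCOD/mgCOD,stoichiometric,0.666,0.333,0.9990000000000001,uniform
X53,Anoxic heterotrophic yield on soluble substrate,mgCOD/mgCOD,stoichiometric,0.533,0.2665,0.7995000000000001,uniform
X16,Aerobic heterotrophic decay rate,1/d,kinetic,0.62,0.23,0.93,uniform
X12,Reduction factor for denitrification on nitrite-N,-,kinetic,0.48,0.24,0.72,uniform
X15,Oxygen inhibition coefficient for denitrification,mgO2/L,kinetic,0.2,0.1,0.30000000000000004,uniform
X61,Unbiodegradable fraction from cell decay,-,stoichiometric,0.08,0.04,0.12,uniform
X27,Maximum growth rate for nitrite oxidizer,1/d,kinetic,0.7,0.35,1.0499999999999998,uniform
X1,Maximum heterotrophic growth rate,1/d,kinetic,4.0,2.0,6.0,uniform
X2,Half-saturation for readily biodegradable substrate,mgCOD/L,kinetic,10.0,5.0,15.0,uniform
X3,Oxygen half-saturation for heterotrophs,mgO2/L,kinetic,0.2,0.1,0.30000000000000004,uniform
X11,Reduction factor for denitrification on nitrate-N,-,kinetic,0.48,0.24,0.72,uniform
X13,Nitrate half-saturation for denitrification,mgN/L,kinetic,0.5,0.25,0.75,uniform
X14,Nitrite half-saturation for denitrification,mgN/L,kinetic,0.5,0.25,0.75,uniform
X21,Maximum growth rate for ammonia oxidizer,1/d,kinetic,0.9,0.45,1.35,uniform
X22,Ammonia half-saturation for ammonia oxidizer,mgN/L,kinetic,0.7,0.35,1.0499999999999998,uniform
X23,Oxygen half-saturation for nitrifiers,mgO2/L,kinetic,0.4,0.2,0.6000000000000001,uniform
X24,Ammonia oxidizer yield,mgCOD/mgN,stoichiometric,0.18,0.09,0.27,uniform
X26,Nitrite oxidizer yield,mgCOD/mgN,stoichiometric,0.06,0.03,0.09,uniform
X28,Nitrite half-saturation for nitrite oxidizer,mgN/L,kinetic,0.5,0.25,0.75,uniform
X17,Ammonia oxidizer decay rate,1/d,kinetic,0.15,0.075,0.22499999999999998,uniform
X18,Nitrite oxidizer decay rate,1/d,kinetic,0.15,0.075,0.22499999999999998,uniform
X31,Maximum specific hydrolysis rate,mgCOD/mgCOD/d,kinetic,3.0,1.5,4.5,uniform
X32,Hydrolysis half-saturation,mgCOD/mgCOD,kinetic,0.1,0.05,0.15000000000000002,uniform
X33,Ammonification rate,m3/gCOD/d,kinetic,0.08,0.04,0.12,uniform
X41,Nitrogen content of biomass,mgN/mgCOD,stoichiometric,0.086,0.043,0.129,uniform
X42,Nitrogen content of endogenous products,mgN/mgCOD,stoichiometric,0.06,0.03,0.09,uniform
X43,Biofilm attachment rate,1/d,kinetic,0.5,0.25,0.75,uniform
X44,Biofilm detachment rate,1/d,kinetic,0.05,0.025,0.07500000000000001,uniform
X4,Registry padding parameter 4 (inert placeholder),-,padding,1.0,0.5,1.5,uniform
X5,Registry padding parameter 5 (inert placeholder),-,padding,1.0,0.5,1.5,uniform
X6,Registry padding parameter 6 (inert placeholder),-,padding,1.0,0.5,1.5,uniform
X7,Registry padding parameter 7 (inert placeholder),-,padding,1.0,0.5,1.5,uniform
X8,Registry padding parameter 8 (inert placeholder),-,padding,1.0,0.5,1.5,uniform
X9,Registry padding parameter 9 (inert placeholder),-,padding,1.0,0.5,1.5,uniform
X10,Registry padding parameter 10 (inert placeholder),-,padding,1.0,0.5,1.5,uniform
X19,Registry padding parameter 19 (inert placeholder),-,padding,1.0,0.5,1.5,uniform
X20,Registry padding parameter 20 (inert placeholder),-,padding,1.0,0.5,1.5,uniform
X25,Registry padding parameter 25 (inert placeholder),-,padding,1.0,0.5,1.5,uniform
X29,Registry padding parameter 29 (inert placeholder),-,padding,1.0,0.5,1.5,uniform
X30,Registry padding parameter 30 (inert placeholder),-,padding,1.0,0.5,1.5,uniform
X34,Registry padding parameter 34 (inert placeholder),-,padding,1.0,0.5,1.5,uniform
X35,Registry padding parameter 35 (inert placeholder),-,padding,1.0,0.5,1.5,uniform
X36,Registry padding parameter 36 (inert placeholder),-,padding,1.0,0.5,1.5,uniform
X37,Registry padding parameter 37 (inert placeholder),-,padding,1.0,0.5,1.5,uniform
X38,Registry padding parameter 38 (inert placeholder),-,padding,1.0,0.5,1.5,uniform
X39,Registry padding parameter 39 (inert placeholder),-,padding,1.0,0.5,1.5,uniform
X40,Registry padding parameter 40 (inert placeholder),-,padding,1.0,0.5,1.5,uniform
X45,Registry padding parameter 45 (inert placeholder),-,padding,1.0,0.5,1.5,uniform
X46,Registry padding parameter 46 (inert placeholder),-,padding,1.0,0.5,1.5,uniform
X47,Registry padding parameter 47 (inert placeholder),-,padding,1.0,0.5,1.5,uniform
X48,Registry padding parameter 48 (inert placeholder),-,padding,1.0,0.5,1.5,uniform
X49,Registry padding parameter 49 (inert placeholder),-,padding,1.0,0.5,1.5,uniform
X50,Registry padding parameter 50 (inert placeholder),-,padding,1.0,0.5,1.5,uniform
X51,Registry padding parameter 51 (inert placeholder),-,padding,1.0,0.5,1.5,uniform
X54,Registry padding parameter 54 (inert placeholder),-,padding,1.0,0.5,1.5,uniform
X55,Registry padding parameter 55 (inert placeholder),-,padding,1.0,0.5,1.5,uniform
X56,Registry padding parameter 56 (inert placeholder),-,padding,1.0,0.5,1.5,uniform
X57,Registry padding parameter 57 (inert placeholder),-,padding,1.0,0.5,1.5,uniform
X58,Registry padding parameter 58 (inert placeholder),-,padding,1.0,0.5,1.5,uniform
X59,Registry padding parameter 59 (inert placeholder),-,padding,1.0,0.5,1.5,uniform
X60,Registry padding parameter 60 (inert placeholder),-,padding,1.0,0.5,1.5,uniform
X62,Registry padding parameter 62 (inert placeholder),-,padding,1.0,0.5,1.5,uniform
X63,Registry padding parameter 63 (inert placeholder),-,padding,1.0,0.5,1.5,uniform
X64,Registry padding parameter 64 (inert placeholder),-,padding,1.0,0.5,1.5,uniform
X65,Registry padding parameter 65 (inert placeholder),-,padding,1.0,0.5,1.5,uniform
X66,Registry padding parameter 66 (inert placeholder),-,padding,1.0,0.5,1.5,uniform
X67,Registry padding parameter 67 (inert placeholder),-,padding,1.0,0.5,1.5,uniform
X68,Registry padding parameter 68 (inert placeholder),-,padding,1.0,0.5,1.5,uniform
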