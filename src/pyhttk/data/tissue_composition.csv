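tissue,f_water,f_neutral_lipid,f_phospholipid,f_protein,pH,vol_frac_BW,flow_frac_QC
adipose,0.18,0.790,0.0020,0.020,7.1,0.2100,0.050
bone,0.44,0.070,0.0010,0.200,7.0,0.0900,0.050
brain,0.77,0.050,0.0500,0.080,7.1,0.0200,0.120
gut,0.76,0.065,0.0160,0.140,7.0,0.0170,0.150
heart,0.76,0.014,0.0110,0.140,7.1,0.0047,0.040
kidney,0.79,0.012,0.0240,0.140,7.2,0.0044,0.190
liver,0.75,0.035,0.0250,0.180,7.0,0.0260,0.065
lung,0.81,0.003,0.0090,0.140,6.6,0.0080,0.000
muscle,0.76,0.024,0.0070,0.170,7.0,0.4000,0.170
skin,0.72,0.028,0.0110,0.160,7.0,0.0370,0.058
spleen,0.78,0.012,0.0120,0.150,7.0,0.0026,0.020
red blood cells,0.63,0.0020,0.0030,0.150,7.2,0.0,0.0
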