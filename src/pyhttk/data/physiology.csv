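parameter,unit,Human,Rat,source
BW,kg,70.0,0.25,reference adult / adult rat
QC,L/h/kg^0.75,15.0,14.0,cardiac output allometric coefficient
Qalv,L/h/kg^0.75,15.0,15.0,alveolar ventilation allometric coefficient
hct,fraction,0.44,0.46,hematocrit
GFR,L/h/kg^0.75,0.31,0.31,glomerular filtration allometric coefficient
liver_mass_frac,g/kg,25.7,34.0,liver mass per kg body weight
hepatocellularity,10^6 cells/g liver,110.0,110.0,hepatocytes per gram liver
body_temperature,K,310.15,310.15,core body temperature
Vart_frac,L/kg,0.025,0.019,arterial blood volume per kg BW
Vven_frac,L/kg,0.050,0.041,venous blood volume per kg BW
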