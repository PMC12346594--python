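collected_enantiomer,analyte,csp,eluent,temperature_c,flow_ml_min,injected_racemate_mg,collected_mg,purity_pct
R-omeprazole,omeprazole,AD,MeOH,40,1.5,30,13.2,99.93
S-rabeprazole,rabeprazole,Cell4,MeOH,10,1.2,20,7.4,99.89
S-lansoprazole,lansoprazole,Cell4,MeOH,10,1.2,20,4.3,99.85
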