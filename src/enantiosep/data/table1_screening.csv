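csp,eluent,analyte,k1,k2,rs,eeo
OD,MeOH,omeprazole,0.20,0.20,-,-
OD,MeOH,rabeprazole,0.23,0.43,2.83,R-S
OD,MeOH,lansoprazole,0.04,0.16,2.25,R-S
OD,EtOH,omeprazole,0.42,0.47,0.57,S-R
OD,EtOH,rabeprazole,0.51,0.69,1.95,R-S
OD,EtOH,lansoprazole,0.33,0.48,1.92,R-S
OD,1-PrOH,omeprazole,0.43,0.43,-,-
OD,1-PrOH,rabeprazole,0.48,0.69,1.55,R-S
OD,1-PrOH,lansoprazole,0.39,0.58,1.60,R-S
OD,2-PrOH,omeprazole,0.88,0.88,-,-
OD,2-PrOH,rabeprazole,1.17,1.17,-,-
OD,2-PrOH,lansoprazole,0.87,1.24,1.38,R-S
Cell2,MeOH,omeprazole,1.02,1.90,7.02,S-R
Cell2,MeOH,rabeprazole,1.54,2.11,3.76,S-R
Cell2,MeOH,lansoprazole,0.53,0.68,2.00,S-R
Cell2,EtOH,omeprazole,1.32,2.18,3.69,S-R
Cell2,EtOH,rabeprazole,2.39,2.60,0.74,S-R
Cell2,EtOH,lansoprazole,0.93,0.93,-,-
Cell2,1-PrOH,omeprazole,1.54,2.41,2.24,S-R
Cell2,1-PrOH,rabeprazole,2.90,2.90,-,-
Cell2,1-PrOH,lansoprazole,1.32,1.32,-,-
Cell2,2-PrOH,omeprazole,3.77,4.89,0.68,S-R
Cell2,2-PrOH,rabeprazole,6.69,6.69,-,-
Cell2,2-PrOH,lansoprazole,2.81,3.65,0.94,S-R
OJ,MeOH,omeprazole,0.23,0.23,-,-
OJ,MeOH,rabeprazole,0.18,0.18,-,-
OJ,MeOH,lansoprazole,0.07,0.07,-,-
OJ,EtOH,omeprazole,0.22,0.22,-,-
OJ,EtOH,rabeprazole,0.15,0.15,-,-
OJ,EtOH,lansoprazole,0.05,0.05,-,-
OJ,1-PrOH,omeprazole,0.27,0.27,-,-
OJ,1-PrOH,rabeprazole,0.19,0.19,-,-
OJ,1-PrOH,lansoprazole,0.13,0.13,-,-
OJ,2-PrOH,omeprazole,0.41,0.41,-,-
OJ,2-PrOH,rabeprazole,0.31,0.31,-,-
OJ,2-PrOH,lansoprazole,0.23,0.23,-,-
Cell4,MeOH,omeprazole,0.85,1.79,6.89,S-R
Cell4,MeOH,rabeprazole,1.35,2.33,6.16,S-R
Cell4,MeOH,lansoprazole,0.40,0.67,3.26,S-R
Cell4,EtOH,omeprazole,1.27,3.03,4.44,S-R
Cell4,EtOH,rabeprazole,2.56,4.11,3.62,S-R
Cell4,EtOH,lansoprazole,0.82,1.33,2.41,S-R
Cell4,1-PrOH,omeprazole,1.45,2.45,2.60,S-R
Cell4,1-PrOH,rabeprazole,3.21,3.97,1.36,S-R
Cell4,1-PrOH,lansoprazole,1.08,1.37,0.97,S-R
Cell4,2-PrOH,omeprazole,3.87,5.69,1.52,S-R
Cell4,2-PrOH,rabeprazole,6.54,6.54,-,-
Cell4,2-PrOH,lansoprazole,3.30,3.73,0.26,S-R
AD,MeOH,omeprazole,1.77,5.88,9.91,S-R
AD,MeOH,rabeprazole,1.19,1.41,1.27,R-S
AD,MeOH,lansoprazole,0.53,0.79,1.33,R-S
AD,EtOH,omeprazole,1.82,2.65,3.95,S-R
AD,EtOH,rabeprazole,1.80,2.14,1.93,S-R
AD,EtOH,lansoprazole,1.02,1.02,-,-
AD,1-PrOH,omeprazole,1.13,2.02,3.59,R-S
AD,1-PrOH,rabeprazole,0.913,1.16,1.67,R-S
AD,1-PrOH,lansoprazole,0.59,0.67,0.72,R-S
AD,2-PrOH,omeprazole,0.53,0.75,1.65,R-S
AD,2-PrOH,rabeprazole,0.573,0.76,1.30,R-S
AD,2-PrOH,lansoprazole,0.35,0.35,-,-
AS,MeOH,omeprazole,0.41,0.54,1.18,S-R
AS,MeOH,rabeprazole,0.38,0.85,3.72,S-R
AS,MeOH,lansoprazole,0.14,0.24,1.19,S-R
AS,EtOH,omeprazole,0.52,0.73,1.27,R-S
AS,EtOH,rabeprazole,0.41,0.69,1.75,R-S
AS,EtOH,lansoprazole,0.15,0.36,1.68,R-S
AS,1-PrOH,omeprazole,0.52,0.72,0.80,R-S
AS,1-PrOH,rabeprazole,0.33,0.71,1.76,R-S
AS,1-PrOH,lansoprazole,0.19,0.53,1.82,R-S
AS,2-PrOH,omeprazole,1.15,2.18,1.73,R-S
AS,2-PrOH,rabeprazole,0.76,1.77,2.22,R-S
AS,2-PrOH,lansoprazole,0.43,1.08,1.80,R-S
IA,MeOH,omeprazole,1.32,2.26,3.45,S-R
IA,MeOH,rabeprazole,0.78,0.90,1.44,R-S
IA,MeOH,lansoprazole,0.35,0.46,1.65,R-S
IA,EtOH,omeprazole,1.39,1.84,2.92,S-R
IA,EtOH,rabeprazole,1.29,1.42,1.08,S-R
IA,EtOH,lansoprazole,0.64,0.69,0.68,S-R
IA,1-PrOH,omeprazole,0.78,1.55,6.02,R-S
IA,1-PrOH,rabeprazole,0.87,1.07,1.75,R-S
IA,1-PrOH,lansoprazole,0.56,0.56,-,-
IA,2-PrOH,omeprazole,0.87,1.09,1.41,R-S
IA,2-PrOH,rabeprazole,0.99,1.15,0.91,R-S
IA,2-PrOH,lansoprazole,0.64,0.64,-,-
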