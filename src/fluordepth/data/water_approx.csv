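# Approximate absorption coefficient of pure water (cm^-1),
# smoothed synthetic rendering of the commonly tabulated curve; fixture data.
wavelength_nm,absorption_cm
500,0.00025
510,0.00030
520,0.00040
530,0.00044
540,0.00056
550,0.00057
560,0.00071
570,0.00080
580,0.00108
590,0.00130
600,0.00220
610,0.00260
620,0.00280
630,0.00300
640,0.00320
650,0.00340
660,0.00400
670,0.00440
680,0.00480
690,0.00520
700,0.00600
710,0.00740
720,0.01000
730,0.01900
740,0.02600
750,0.02600
760,0.02700
770,0.02400
780,0.02200
790,0.02100
800,0.02000
810,0.02100
820,0.02400
830,0.02900
840,0.03600
850,0.04300
860,0.04800
870,0.05200
880,0.05600
890,0.06100
900,0.06800
910,0.09000
920,0.12000
930,0.18000
940,0.27000
950,0.37000
960,0.42000
970,0.46000
980,0.43000
990,0.39000
1000,0.36000
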