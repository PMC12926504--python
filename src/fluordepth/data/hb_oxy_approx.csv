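# Approximate molar extinction coefficient of oxyhemoglobin (cm^-1 / M),
# smoothed synthetic rendering of the commonly tabulated curve; fixture data.
wavelength_nm,extinction_cm_M
500,20932
510,20035
520,24202
530,39036
540,53236
550,43016
560,32613
570,44496
580,50104
590,7000
600,3200
610,1506
620,942
630,610
640,442
650,368
660,320
670,294
680,277
690,276
700,290
710,314
720,362
730,390
740,446
750,518
760,586
770,650
780,710
790,756
800,816
810,864
820,916
830,945
840,980
850,1058
860,1104
870,1136
880,1167
890,1190
900,1198
910,1195
920,1190
930,1175
940,1160
950,1130
960,1100
970,1050
980,1000
990,950
1000,900
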