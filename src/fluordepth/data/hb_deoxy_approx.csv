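# Approximate molar extinction coefficient of deoxyhemoglobin (cm^-1 / M),
# smoothed synthetic rendering of the commonly tabulated curve; fixture data.
wavelength_nm,extinction_cm_M
500,20862
510,25773
520,31589
530,39437
540,46592
550,52276
560,53907
570,45072
580,37020
590,22000
600,14700
610,10300
620,7430
630,5900
640,4930
650,3750
660,3227
670,2550
680,2400
690,2100
700,1794
710,1500
720,1300
730,1150
740,1350
750,1550
760,1670
770,1380
780,1100
790,940
800,830
810,790
820,760
830,735
840,710
850,691
860,690
870,700
880,710
890,720
900,730
910,745
920,760
930,780
940,800
950,820
960,840
970,860
980,880
990,900
1000,920
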