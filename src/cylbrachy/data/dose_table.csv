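diameter_cm,dose_5mm_cGy,dose_surface_cGy
2.5,300,500
2.5,400,660
2.5,430,700
2.5,500,800
2.5,550,880
2.5,600,950
2.5,700,1100
2.5,800,1250
2.5,850,1350
3.0,340,500
3.0,400,600
3.0,430,640
3.0,500,730
3.0,550,830
3.0,600,910
3.0,700,1050
3.0,800,1200
3.0,850,1300
3.5,360,500
3.5,400,550
3.5,430,590
3.5,500,710
3.5,550,810
3.5,600,890
3.5,700,1000
3.5,800,1150
3.5,850,1250
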