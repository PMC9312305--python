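diameter_cm,direction,a,b,c,d,e,f
2.5,to_surface,0.004975,-0.140437,1.550614,-8.351723,23.370814,-21.646311
3.0,to_surface,0.007740,-0.219375,2.427377,-13.101861,36.031033,-35.645704
3.5,to_surface,-0.004073,0.158500,-2.295163,15.633410,-48.875896,61.292976
2.5,to_5mm,-0.000316,0.014380,-0.256824,2.245143,-8.909707,15.522264
3.0,to_5mm,-0.000461,0.019668,-0.326899,2.645898,-9.778320,16.149188
3.5,to_5mm,0.000448,-0.023634,0.472499,-4.488110,20.930508,-34.560913
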