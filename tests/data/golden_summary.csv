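scenario,suitable_km2,pct_dec_suitable,optimal_km2,pct_dec_optimal,W,p
current,5522.7,0,1049.8,0,,
warm_low,5375.7,2.7,973.5,7.3,433294,0.778511
warm_mid,5240.1,5.1,914.8,12.9,425614,0.573318
warm_high,5145.9,6.8,867.9,17.3,418729,0.530229
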