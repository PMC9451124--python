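study,region,gender,age,categories,rr,ci_low,ci_high
jacobs,"Europe, US, Japan",M,40-59,light,1.30,1.20,1.40
jacobs,"Europe, US, Japan",M,40-59,moderate;heavy,1.80,1.70,1.90
gellert,"US, China, Aus, Japan",M/F,60+,light;moderate;heavy,1.83,1.65,2.03
gellert,"US, China, Aus, Japan",M/F,60+,former,1.34,1.28,1.40
carter,US,M,55+,light;moderate;heavy,2.80,2.80,2.90
carter_f,US,F,55+,light;moderate;heavy,2.80,2.70,2.90
shavelle,"US, Asia, Europe",M/F,adults,light,1.47,1.37,1.80
shavelle,"US, Asia, Europe",M/F,adults,moderate,2.02,1.84,2.36
shavelle,"US, Asia, Europe",M/F,adults,heavy,2.38,2.17,2.84
shavelle,"US, Asia, Europe",M/F,adults,former,1.31,1.07,1.39
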