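genotype,trait,mean,sem,n,provenance
---,conv,8.0,0.5,2,assumed
---,ddg,0.0,0.0,2,reported
---,ncr,150.0,4.0,2,assumed
---,pfr,24.0,1.0,2,derived
---,ce,16.0,1.0,2,assumed
---,ttn,110.0,10.0,2,assumed
---,ttf,11.0,1.0,2,reported
I--,conv,6.5,0.5,2,assumed
I--,ddg,-1.0,0.144338,2,assumed
I--,ncr,145.0,4.0,2,assumed
I--,pfr,21.75,1.0,2,derived
I--,ce,15.0,1.0,2,assumed
I--,ttn,80.0,8.0,2,assumed
I--,ttf,7.0,1.0,2,solved
-I-,conv,7.5,0.5,2,assumed
-I-,ddg,-4.2,0.144338,2,assumed
-I-,ncr,150.0,4.0,2,assumed
-I-,pfr,24.0,1.0,2,derived
-I-,ce,16.0,1.0,2,assumed
-I-,ttn,100.0,9.0,2,assumed
-I-,ttf,11.0,1.0,2,solved
--I,conv,10.0,0.6,2,assumed
--I,ddg,1.75,0.144338,2,assumed
--I,ncr,155.0,4.0,2,assumed
--I,pfr,34.1,1.2,2,derived
--I,ce,22.0,1.0,2,assumed
--I,ttn,210.0,15.0,2,assumed
--I,ttf,21.0,2.0,2,reported
II-,conv,6.4,0.5,2,solved
II-,ddg,-2.4,0.1,2,solved
II-,ncr,143.7,4.0,2,solved
II-,pfr,21.555,1.0,2,derived
II-,ce,15.0,1.0,2,assumed
II-,ttn,79.0,8.0,2,solved
II-,ttf,9.0,1.0,2,solved
I-I,conv,10.5,0.6,2,solved
I-I,ddg,3.35,0.1,2,solved
I-I,ncr,173.0,5.0,2,solved
I-I,pfr,41.52,1.5,2,derived
I-I,ce,24.0,1.0,2,assumed
I-I,ttn,218.0,15.0,2,solved
I-I,ttf,24.0,2.0,2,solved
-II,conv,34.5,1.0,2,solved
-II,ddg,3.15,0.1,2,solved
-II,ncr,246.0,6.0,2,solved
-II,pfr,91.02,2.4,2,derived
-II,ce,37.0,1.0,2,reported
-II,ttn,690.0,30.0,2,solved
-II,ttf,72.0,4.0,2,reported
III,conv,35.0,1.0,2,solved
III,ddg,5.6,0.0,2,reported
III,ncr,433.0,4.0,2,solved
III,pfr,160.21,1.5,2,derived
III,ce,37.0,1.0,2,reported
III,ttn,718.0,30.0,2,solved
III,ttf,158.0,6.0,2,reported
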