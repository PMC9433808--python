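subject_id,AGE,ERD,HBO,BBS
P1,60,-1.834,1.905,55
P2,74,-0.396,1.999,33
P3,49,-1.977,0.211,40
P4,64,-0.695,0.098,8
P5,33,-0.979,2.925,46
P6,32,-0.448,2.066,55
P7,67,-0.825,1.170,40
P8,49,-0.790,2.000,40
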