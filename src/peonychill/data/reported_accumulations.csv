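treatment_id,transfer_date,ch,cu
Tre. 1-1,2012-11-26,0.00,0.00
Tre. 1-2,2012-12-10,46.00,117.47
Tre. 1-3,2012-12-24,250.00,334.84
Tre. 1-4,2013-01-07,483.00,615.27
Tre. 1-5,2013-01-21,738.00,856.08
Tre. 1-6,2013-02-04,892.00,1009.45
Tre. 1-7,2013-02-25,1170.00,1311.58
Tre. 1-8,2013-03-11,1238.00,1383.20
Tre. 2-1,2013-11-29,0.00,0.00
Tre. 2-2,2013-12-06,168.00,147.67
Tre. 2-3,2013-12-13,336.00,295.34
Tre. 2-4,2013-12-20,504.00,443.02
Tre. 2-5,2013-12-27,672.00,590.69
Tre. 2-6,2014-01-03,840.00,738.36
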