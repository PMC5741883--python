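treatment_id,experiment,mode,chill_start,chill_end,storage_temp
Tre. 1-1,natural_2012,natural,,2012-11-26 10:00,
Tre. 1-2,natural_2012,natural,,2012-12-10 10:00,
Tre. 1-3,natural_2012,natural,,2012-12-24 10:00,
Tre. 1-4,natural_2012,natural,,2013-01-07 10:00,
Tre. 1-5,natural_2012,natural,,2013-01-21 10:00,
Tre. 1-6,natural_2012,natural,,2013-02-04 10:00,
Tre. 1-7,natural_2012,natural,,2013-02-25 10:00,
Tre. 1-8,natural_2012,natural,,2013-03-11 10:00,
Tre. 2-1,artificial_2013,artificial,2013-11-29 09:00,2013-11-29 09:00,2.0
Tre. 2-2,artificial_2013,artificial,2013-11-29 09:00,2013-12-06 09:00,2.0
Tre. 2-3,artificial_2013,artificial,2013-11-29 09:00,2013-12-13 09:00,2.0
Tre. 2-4,artificial_2013,artificial,2013-11-29 09:00,2013-12-20 09:00,2.0
Tre. 2-5,artificial_2013,artificial,2013-11-29 09:00,2013-12-27 09:00,2.0
Tre. 2-6,artificial_2013,artificial,2013-11-29 09:00,2014-01-03 09:00,2.0
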