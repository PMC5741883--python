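winter,date,interval_ch,cumulative_ch
2012-2013,2012-11-26,0,0
2012-2013,2012-12-10,103,103
2012-2013,2012-12-24,204,307
2012-2013,2013-01-21,488,795
2012-2013,2013-02-04,154,949
2012-2013,2013-02-25,278,1227
2015-2016,2015-11-26,33,33
2015-2016,2015-12-10,128,161
2015-2016,2015-12-24,107,268
2015-2016,2016-01-21,331,599
2015-2016,2016-02-04,258,857
2015-2016,2016-02-25,227,1084
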