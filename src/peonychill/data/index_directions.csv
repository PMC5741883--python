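index_code,description,higher_is_better
BBP,Bud break percentage 5 weeks after transfer,true
FBP,Final bud break percentage after transfer,true
DEA,Days from transfer to visible stem elongation for all plants,false
ANS,Number of mature normal stems per plant,true
APH,Average plant height at full flowering,true
APW,Average plant width at full flowering,true
NSP,Number of small bud points per plant,true
NAB,Number of abnormal buds per plant,true
NPO,Number of plants with opening flower per replicate,true
NOF,Number of opening flowers per replicate,true
ANO,Average number of opening flowers per plant,true
ANA,Average number of aborted flowers per plant,true
POF,Percentage of opening flowers per plant,true
PAF,Percentage of aborted flowers per plant,false
ADF,Average diameter of flowers,true
ADS,Average diameter of flower stems,true
AOD,Average opening days per flower,true
NDF,Sustaining days of full flowering,true
PFF,Period of full flowering,true
DFS,Days from transfer to first plant sprouting,false
DFF,Days from transfer to first flowering,false
PPO,Percentage of plants with opening flower per replicate,true
RCC,Relative chlorophyll content of leaves,true
ALL,Average leaf length at full flowering,true
ALW,Average leaf width at full flowering,true
ALT,Average leaf thickness at full flowering,true
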