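abbreviation,full_name,count
HSP/HSC/HSF,HEAT SHOCK PROTEIN / HEAT SHOCK COGNATE PROTEIN / HEAT SHOCK TRANSCRIPTION FACTOR,17
BIP1,BINDING PROTEIN,1
ERD2,EARLY-RESPONSIVE TO DEHYDRATION 2,1
OSM,OSMOTIN,6
LOS1,LOW EXPRESSION OF OSMOTICALLY RESPONSIVE GENES 1,5
AGL20/SOC1,AGAMOUS-LIKE 20 / SUPPRESSOR OF OVEREXPRESSION OF CONSTANS1,2
COR47,COLD-REGULATED 47,4
WRKY33,WRKY DNA-BINDING PROTEIN 33,1
ATDGK2,DIACYLGLYCEROL KINASE 2,1
ATPP2CA,PROTEIN PHOSPHATASE 2CA,1
GAPB,GLYCERALDEHYDE-3-PHOSPHATE DEHYDROGENASE B SUBUNIT,1
LTI30,LOW TEMPERATURE-INDUCED 30,1
RAB18,RESPONSIVE TO ABA 18,1
RCI2B,RARE-COLD-INDUCIBLE 2B,1
SEX1,STARCH EXCESS 1,1
TCH4,TOUCH 4,2
PAP2,PHYTOCHROME-ASSOCIATED PROTEIN 2,1
LHCB4.2,LIGHT HARVESTING COMPLEX PHOTOSYSTEM II,1
PGK,PHOSPHOGLYCERATE KINASE,1
ATNADP-ME3,NADP-MALIC ENZYME 3,1
CAM8,CALMODULIN 8,1
F11M15.26,F11M15.26,1
LHCA6,PHOTOSYSTEM I LIGHT HARVESTING COMPLEX GENE 6,1
PCK1,PHOSPHOENOLPYRUVATE CARBOXYKINASE 1,2
PCK2,PHOSPHOENOLPYRUVATE CARBOXYKINASE 2,1
PSBP-1,PHOTOSYSTEM II SUBUNIT P-1,1
SBPASE,SEDOHEPTULOSE-BISPHOSPHATASE,2
LHY,LATE ELONGATED HYPOCOTYL,1
TOC1,TIMING OF CAB EXPRESSION 1,1
APRR3,PSEUDO-RESPONSE REGULATOR 3,2
No Arabidopsis gene name,,3
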