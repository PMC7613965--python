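gender,age_band,region,year,treatment,deaths_linked,person_years,deaths_unlinked,cohort_count,population
male,young,england,2005/06,on,55,32454,,,
male,young,england,2005/06,off,42,12160,,,
male,old,england,2005/06,on,35,24155,,,
male,old,england,2005/06,off,42,5945,,,
female,young,england,2005/06,on,14,15506,,,
female,young,england,2005/06,off,5,4016,,,
female,old,england,2005/06,on,9,8524,,,
female,old,england,2005/06,off,8,1643,,,
male,young,england,2006/07,on,50,36073,,,
male,young,england,2006/07,off,33,14389,,,
male,old,england,2006/07,on,39,30133,,,
male,old,england,2006/07,off,39,7988,,,
female,young,england,2006/07,on,10,17223,,,
female,young,england,2006/07,off,7,4507,,,
female,old,england,2006/07,on,9,10484,,,
female,old,england,2006/07,off,8,2122,,,
male,young,england,2007/08,on,45,38004,,,
male,young,england,2007/08,off,35,16999,,,
male,old,england,2007/08,on,72,36063,,,
male,old,england,2007/08,off,32,10042,,,
female,young,england,2007/08,on,11,18113,,,
female,young,england,2007/08,off,5,4750,,,
female,old,england,2007/08,on,16,12262,,,
female,old,england,2007/08,off,5,2604,,,
male,young,england,2008/09,on,38,38995,113,70616,7000000
male,young,england,2008/09,off,31,16257,113,70616,7000000
male,old,england,2008/09,on,55,41937,123,59483,10200000
male,old,england,2008/09,off,24,10714,123,59483,10200000
female,young,england,2008/09,on,9,18815,15,27935,6900000
female,young,england,2008/09,off,0,4510,15,27935,6900000
female,old,england,2008/09,on,20,13962,22,18295,10400000
female,old,england,2008/09,off,4,2742,22,18295,10400000
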