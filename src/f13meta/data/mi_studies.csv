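# f13meta-study-schema v1
study_id,population,disease,n_cases,cases_vv,cases_vl,cases_ll,cases_carriers,n_controls,controls_vv,controls_vl,controls_ll,controls_carriers,nos_score
Alkhiary2016,Egypt,MI,31,24,7,0,,20,15,4,1,,7
Ambroziak2019,Poland,MI,143,76,48,19,,150,85,53,12,,8
ATVB2003,Italy,MI,1210,779,375,56,,1210,789,363,58,,9
Butt2003,Canada,MI,46,,,,19,373,,,,176,6
Franco2000,Brazil,MI,150,96,50,4,,150,77,61,12,,8
Hancer2006,Turkey,MI,95,85,10,0,,112,68,44,0,,9
Mohammad2021,Iraq,MI,102,76,22,4,,77,55,21,1,,8
Rallidis2008,Greece,MI,159,111,43,5,,121,64,50,7,,8
Reiner2002,USA,MI,68,41,24,3,,345,187,138,20,,8
Roldan2005,Spain,MI,30,19,6,5,,585,368,195,22,,7
Siegerink2009,Netherlands,MI,218,124,80,14,,747,419,283,45,,6
Silvain2011,France,MI,242,141,87,14,,242,128,99,15,,8
Vishwajeet2021,India,MI,101,73,27,1,,103,81,20,2,,8
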