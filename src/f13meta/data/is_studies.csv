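# f13meta-study-schema v1
study_id,population,disease,n_cases,cases_vv,cases_vl,cases_ll,cases_carriers,n_controls,controls_vv,controls_vl,controls_ll,controls_carriers,nos_score
Pruissen2008,Netherlands,IS,189,121,60,8,,747,419,283,45,,8
Ranellou2015,Greece,IS,38,18,19,1,,66,38,22,6,,8
Reiner2002,USA,IS,36,16,14,6,,345,187,138,20,,8
Salomi2016,India,IS,105,88,15,2,,215,192,22,1,,9
Shemirani2014,Hungary,IS,159,91,61,7,,159,83,67,9,,9
Wypasek2012,Poland,IS,100,44,51,5,,107,72,30,5,,6
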