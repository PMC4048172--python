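subject_id,group,age,sex,hand,ethnicity,threshold_mA,duration_years
CP01,chronic,56,F,R,C,0.8,0.5
CP02,chronic,65,F,A,C,0.75,0.5
CP03,chronic,52,F,R,C,0.6,5
CP04,chronic,61,F,R,C,1.0,2
CP05,chronic,55,M,L,C,1.8,1
CP06,chronic,46,F,R,C,0.3,1
CP07,chronic,47,F,R,C,0.5,2
CP08,chronic,43,M,R,C,1.2,5
CP09,chronic,46,M,R,B,1.1,0.5
CP10,chronic,52,F,R,B,0.5,5
CP11,chronic,56,F,R,C,0.5,5
CP12,chronic,49,M,L,C,1.0,5
CP13,chronic,46,F,R,B,0.6,0.5
NC01,normal,39,F,R,C,1.2,
NC02,normal,42,F,L,C,0.5,
NC03,normal,62,M,A,C,0.4,
NC04,normal,50,F,R,C,0.8,
NC05,normal,59,F,R,C,0.6,
NC06,normal,47,M,R,B,0.8,
NC07,normal,46,F,R,B,0.5,
NC08,normal,51,F,R,C,0.7,
NC09,normal,59,F,R,C,0.6,
NC10,normal,44,F,R,C,0.9,
NC11,normal,38,M,L,C,0.6,
NC12,normal,40,F,R,C,0.5,
NC13,normal,56,M,R,B,0.5,
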