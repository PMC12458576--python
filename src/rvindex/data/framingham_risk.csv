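sex,points,risk_pct
female,-2,0.9
female,-1,1.0
female,0,1.2
female,1,1.5
female,2,1.7
female,3,2.0
female,4,2.4
female,5,2.8
female,6,3.3
female,7,3.9
female,8,4.5
female,9,5.3
female,10,6.3
female,11,7.3
female,12,8.6
female,13,10.0
female,14,11.7
female,15,13.7
female,16,15.9
female,17,18.5
female,18,21.5
female,19,24.8
female,20,28.5
female,21,30.0
male,-3,0.9
male,-2,1.1
male,-1,1.4
male,0,1.6
male,1,1.9
male,2,2.3
male,3,2.8
male,4,3.3
male,5,3.9
male,6,4.7
male,7,5.6
male,8,6.7
male,9,7.9
male,10,9.4
male,11,11.2
male,12,13.2
male,13,15.6
male,14,18.4
male,15,21.6
male,16,25.3
male,17,29.4
male,18,30.0
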