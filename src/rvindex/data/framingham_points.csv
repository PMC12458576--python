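sex,factor,lower,upper,points
female,age,30,34,0
female,age,35,39,2
female,age,40,44,4
female,age,45,49,5
female,age,50,54,7
female,age,55,59,8
female,age,60,64,9
female,age,65,69,10
female,age,70,74,11
female,age,75,inf,12
female,hdl_cholesterol,60,inf,-2
female,hdl_cholesterol,50,59,-1
female,hdl_cholesterol,45,49,0
female,hdl_cholesterol,35,44,1
female,hdl_cholesterol,-inf,34,2
female,total_cholesterol,-inf,159,0
female,total_cholesterol,160,199,1
female,total_cholesterol,200,239,3
female,total_cholesterol,240,279,4
female,total_cholesterol,280,inf,5
female,sbp_untreated,-inf,119,-3
female,sbp_untreated,120,129,0
female,sbp_untreated,130,139,1
female,sbp_untreated,140,149,2
female,sbp_untreated,150,159,4
female,sbp_untreated,160,inf,5
female,sbp_treated,-inf,119,-1
female,sbp_treated,120,129,2
female,sbp_treated,130,139,3
female,sbp_treated,140,149,5
female,sbp_treated,150,159,6
female,sbp_treated,160,inf,7
female,smoker,1,1,3
female,diabetic,1,1,4
male,age,30,34,0
male,age,35,39,2
male,age,40,44,5
male,age,45,49,6
male,age,50,54,8
male,age,55,59,10
male,age,60,64,11
male,age,65,69,12
male,age,70,74,14
male,age,75,inf,15
male,hdl_cholesterol,60,inf,-2
male,hdl_cholesterol,50,59,-1
male,hdl_cholesterol,45,49,0
male,hdl_cholesterol,35,44,1
male,hdl_cholesterol,-inf,34,2
male,total_cholesterol,-inf,159,0
male,total_cholesterol,160,199,1
male,total_cholesterol,200,239,2
male,total_cholesterol,240,279,3
male,total_cholesterol,280,inf,4
male,sbp_untreated,-inf,119,-2
male,sbp_untreated,120,129,0
male,sbp_untreated,130,139,1
male,sbp_untreated,140,159,2
male,sbp_untreated,160,inf,3
male,sbp_treated,-inf,119,0
male,sbp_treated,120,129,2
male,sbp_treated,130,139,3
male,sbp_treated,140,159,4
male,sbp_treated,160,inf,5
male,smoker,1,1,4
male,diabetic,1,1,3
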