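name,policy,category,flow,main,low,high,include_in_nsb
police,status_quo,direct_intervention,cost,22.1,11.76,31.98,true
court,status_quo,direct_intervention,cost,4.8,3.6,6.16,true
prosecution_legal_aid,status_quo,direct_intervention,cost,3.2,0.7,5.8,true
penalties_corrections,status_quo,direct_intervention,cost,27.0,20.2,33.7,true
merit,status_quo,direct_intervention,cost,3.5,2.64,4.4,true
treatment_cud,status_quo,other_agencies,cost,6.8,6.2,7.5,true
schizophrenia_psychosis,status_quo,other_agencies,cost,6.2,4.7,8.1,true
low_birth_weight,status_quo,other_agencies,cost,1.6,0.5,5.9,true
motor_vehicle_accidents,status_quo,other_agencies,cost,2.3,2.2,6.9,true
fines,status_quo,other_agencies,cost,1.3,0.9,1.6,true
parents_lost_work_time,status_quo,other_agencies,cost,0.1,0.04,0.07,true
defence_attorney,status_quo,other_agencies,cost,1.2,0.9,1.6,true
lost_wages_incarcerated,status_quo,individual_benefits,disbenefit,8.7,6.5,14.5,true
stigma,status_quo,individual_benefits,disbenefit,7.4,1.3,15.1,true
vosly_accidents,status_quo,externalities,disbenefit,3.0,2.3,3.8,true
wellbeing,status_quo,individual_benefits,benefit,579.1,434.3,723.9,true
education_attainment,status_quo,individual_benefits,disbenefit,197.3,157.8,236.7,true
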