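name,policy,category,flow,main,low,high,include_in_nsb
police_drug_driving,legalised_regulated,direct_intervention,cost,11.5,2.3,18.4,true
merit,legalised_regulated,direct_intervention,cost,2.5,1.9,3.1,true
regulatory_agency,legalised_regulated,direct_intervention,cost,1.0,0.7,1.4,true
enforcing_regulations,legalised_regulated,direct_intervention,cost,4.0,1.4,6.5,true
consumer_information_quit,legalised_regulated,direct_intervention,cost,12.5,5.9,18.8,true
treatment_cud,legalised_regulated,other_agencies,cost,10.8,7.4,12.5,true
schizophrenia_psychosis,legalised_regulated,other_agencies,cost,7.1,5.3,9.2,true
low_birth_weight,legalised_regulated,other_agencies,cost,2.9,0.5,7.3,true
motor_vehicle_accidents,legalised_regulated,other_agencies,cost,3.7,2.6,8.3,true
personal_licence,legalised_regulated,direct_intervention,cost,31.1,23.3,38.9,true
fines_regulatory,legalised_regulated,other_agencies,cost,3.2,2.2,4.0,true
growers_compliance,legalised_regulated,direct_intervention,cost,0.5,0.4,0.5,true
vosly_accidents,legalised_regulated,externalities,disbenefit,4.75,3.38,5.94,true
wellbeing,legalised_regulated,individual_benefits,benefit,645.5,484.2,786.8,true
education_attainment,legalised_regulated,individual_benefits,disbenefit,323.0,258.4,386.7,true
payments_to_growers,legalised_regulated,direct_intervention,revenue_expense,617.5,385.9,790.2,false
operating_shops,legalised_regulated,direct_intervention,revenue_expense,82.86,47.74,450.1,false
gross_revenue,legalised_regulated,direct_intervention,revenue,1360,1263,1437,false
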