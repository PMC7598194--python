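# Dosing-regimen fixture library: one row per clinical study arm used for building
# (adults) and evaluating (pediatrics) the model. Regimens, demographics and sampling
# sites are transcribed from the published study overview tables; the observed
# concentrations themselves are external literature data and are NOT encoded here.
# bolus_dose: bolus / short-infusion dose (ug/kg when bolus_per_kg=1, otherwise ug);
# bolus_duration_min = 0 means a true bolus. infusion_rate: long-term infusion rate
# (ug/kg/h when infusion_per_kg=1, otherwise ug/h) over infusion_duration_h.
# age_years is chronological age; gestational_weeks defaults to 40 when unreported.
# dataset: i = internal training, e = external test, p = pediatric evaluation.
study_id,n,female_pct,age_years,gestational_weeks,weight_kg,bolus_dose,bolus_per_kg,bolus_duration_min,infusion_rate,infusion_per_kg,infusion_duration_h,site,analytes,dataset,ddi
bentley_1982_adult,5,100,36,40,64,10.0,1,0,,,,arterial,fentanyl,e,0
bentley_1982_elderly,4,100,67,40,68,10.0,1,0,,,,arterial,fentanyl,e,0
bovill_1980,5,40,57,40,71,60.0,1,2,,,,venous,fentanyl,e,0
christrup_2008,7,43,24,40,68,1.5,1,0,,,,venous,fentanyl,i,0
duthie_1986_1,10,50,61,40,69,1.4,1,0,100.0,0,24,venous,fentanyl,e,0
duthie_1986_2,13,50,49,40,65,1.5,1,0,100.0,0,24,venous,fentanyl,e,0
duthie_1986_3,10,50,58,40,69,1.4,1,0,100.0,0,24,venous,fentanyl,e,0
duthie_1986_4,12,50,55,40,69,7.2,1,0,100.0,0,26,venous,fentanyl,i,0
gourlay_1989,6,50,35,40,70,1.0,1,1,,,,venous,fentanyl,e,0
gupta_1995,6,0,35,40,73,,,,50.0,0,48,venous,fentanyl,i,0
holley_1988_1,10,0,54,40,76,1.3,1,2,25.0,0,24,arterial,fentanyl,i,0
holley_1988_2,10,0,44,40,81,2.5,1,2,50.0,0,24,arterial,fentanyl,e,0
holley_1988_3,10,0,56,40,80,5.0,1,2,100.0,0,24,arterial,fentanyl,e,0
holley_1988_4,9,0,54,40,77,6.5,1,2,125.0,0,24,arterial,fentanyl,i,0
lim_2012,22,58,23,40,67,1.5,1,5,,,,venous,fentanyl,e,0
macleod_2012,10,51,25,40,73,0.3,1,0.083,,,,arterial,fentanyl,i,0
mcclain_1980,5,0,25,40,75,6.4,1,1.5,,,,arterial,fentanyl,i,0
saari_2008,12,42,35,40,73,5.0,1,2,,,,venous,fentanyl+norfentanyl,e,0
saari_2008_ddi,12,42,35,40,73,5.0,1,2,,,,venous,fentanyl+norfentanyl,e,1
singleton_1987_1,7,50,33,40,73,20.7,1,2,,,,arterial,fentanyl,e,0
stoeckel_1982,3,33,22,40,66,7.6,1,0,,,,venous,fentanyl,e,0
streisand_1991,10,0,27,40,76,15.0,1,8,,,,arterial,fentanyl,e,0
varvel_1989,8,63,45,40,68,11.4,1,5,,,,arterial,fentanyl,e,0
ziesenitz_2015,16,25,33,40,73,5.0,1,10,,,,venous,fentanyl+norfentanyl,i,0
collins_1985,9,22,0.0,32,1.1,30.0,1,1,,,,arterial,fentanyl,p,0
gauntlett_1988_1,1,50,0.0027,38,2.8,52.5,1,2,,,,arterial,fentanyl,p,0
gauntlett_1988_2,1,50,0.0082,40,2.5,56.5,1,2,,,,arterial,fentanyl,p,0
gauntlett_1988_all,14,50,0.049,38,2.7,54.1,1,2,,,,arterial,fentanyl,p,0
koehntop_1986_1,1,50,0.0055,40,2.0,25.0,1,2,,,,arterial,fentanyl,p,0
koehntop_1986_2,1,50,0.0055,40,3.5,50.0,1,2,,,,arterial,fentanyl,p,0
koehntop_1986_all,14,50,0.0082,40,2.9,30.0,1,2,,,,arterial,fentanyl,p,0
saarenmaa_2000,38,26,0.0011,32,1.8,10.5,1,60,1.5,1,58,arterial,fentanyl,p,0
singleton_1987_2,7,50,0.542,40,7.8,31.2,1,2,,,,arterial,fentanyl,p,0
singleton_1987_3,7,50,2.7,40,13.9,30.8,1,2,,,,venous,fentanyl,p,0
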