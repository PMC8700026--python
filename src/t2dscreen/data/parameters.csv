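name,mean,se,se_kind,n_obs,dist,dsa_rule,domain,units,source
prev_t2dm_30,0.0631,0.00002,se,,beta,pct20,probability,proportion,national survey
prev_t2dm_35,0.0683,0.00003,se,,beta,pct20,probability,proportion,national survey
prev_t2dm_40,0.0743,0.00004,se,,beta,pct20,probability,proportion,national survey
prev_t2dm_45,0.0814,0.00005,se,,beta,pct20,probability,proportion,national survey
sens_findrisc,0.864,0.082,se,,beta,ci95,probability,proportion,validation study
spec_findrisc,0.583,0.031,se,,beta,ci95,probability,proportion,validation study
sens_fcg,0.842,0.003,se,,beta,ci95,probability,proportion,validation study
spec_fcg,0.766,0.001,se,,beta,ci95,probability,proportion,validation study
sens_fpg,0.544,0.006,se,,beta,ci95,probability,proportion,validation study
spec_fpg,0.989,0.0004,se,,beta,ci95,probability,proportion,validation study
hba1c_undx,8.5,2.5,se,,normal,ci95,hba1c,percent,cohort study
hba1c_dx,7.0,1.5,se,,normal,ci95,hba1c,percent,trial usual-care arm
hba1c_comp,9.1,2.4,se,,normal,ci95,hba1c,percent,cohort study
rr_death_t2dm,1.89,0.077,se,,lognormal,ci95,ratio,relative risk,meta-analysis
rr_death_per_hba1c,1.38,0.048,se,,lognormal,ci95,ratio,relative risk per 1% HbA1c,cohort study
rr_comp_per_hba1c,1.40,0.036,se,,lognormal,ci95,ratio,relative risk per 1% HbA1c,cohort study
p_ngt_undx,0.0067,0.0011,se,,beta,pct20,probability,annual probability,cohort study
p_ngt_dx,0.0067,0.0011,se,,beta,pct20,probability,annual probability,cohort study
p_undx_dx,0.0352,0.0102,se,,beta,pct20,probability,annual probability,cohort study
p_undx_comp,0.0231,0.000001,se,,beta,pct20,probability,annual probability,derived
p_dx_comp,0.0140,0.000001,se,,beta,pct20,probability,annual probability,follow-up study
cost_test_findrisc,0.3,0,se,,fixed,pct20,positive,US$,estimated
cost_test_fcg,0.7,0,se,,fixed,pct20,positive,US$,national price list
cost_test_fpg,0.9,0,se,,fixed,pct20,positive,US$,national price list
cost_tx_dx_med,66.0,76945,patient_variance,1631,gamma,pct20,positive,US$/year,primary data
cost_tx_undx_med,17.9,0,se,,fixed,pct20,positive,US$/year,assumed
cost_tx_comp_med,160.1,86476,patient_variance,1631,gamma,pct20,positive,US$/year,primary data
cost_visit_chs,0.6,0,se,,fixed,pct20,positive,US$,estimated
cost_visit_dhc,1.96,0,se,,fixed,pct20,positive,US$,estimated
cost_tx_dx_nonmed,228.1,684856,patient_variance,218,gamma,pct20,positive,US$/year,primary data
cost_tx_undx_nonmed,99.6,0,se,,fixed,pct20,positive,US$/year,assumed
cost_tx_comp_nonmed,327.1,189641,patient_variance,218,gamma,pct20,positive,US$/year,primary data
u_ngt,0.91,0.0038,se,,beta,ci95,utility,utility,population norms
u_undx,0.91,0.0038,se,,beta,ci95,utility,utility,assumed
u_dx,0.89,0.02,se,,beta,ci95,utility,utility,primary data
u_comp,0.63,0.02,se,,beta,ci95,utility,utility,primary data
adherence_referral,1.0,0,se,,fixed,none,probability,proportion,assumed
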