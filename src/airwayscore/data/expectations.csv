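stat_id,expected,decimals,source
bmi.tp,39,0,published per-predictor table (BMI)
bmi.fp,9,0,published per-predictor table (BMI)
bmi.fn,43,0,published per-predictor table (BMI)
bmi.tn,109,0,published per-predictor table (BMI)
bmi.sensitivity_pct,47.56,2,published per-predictor table (BMI)
bmi.specificity_pct,92.37,2,published per-predictor table (BMI)
retrognathia.tp,17,0,published per-predictor table (retrognathia)
retrognathia.fp,11,0,published per-predictor table (retrognathia)
retrognathia.fn,65,0,published per-predictor table (retrognathia)
retrognathia.tn,107,0,published per-predictor table (retrognathia)
retrognathia.sensitivity_pct,20.73,2,published per-predictor table (retrognathia)
retrognathia.specificity_pct,90.68,2,published per-predictor table (retrognathia)
ulbt.tp,17,0,published per-predictor table (ULBT)
ulbt.fp,6,0,published per-predictor table (ULBT)
ulbt.fn,65,0,published per-predictor table (ULBT)
ulbt.tn,112,0,published per-predictor table (ULBT)
ulbt.sensitivity_pct,20.73,2,published per-predictor table (ULBT)
ulbt.specificity_pct,94.92,2,published per-predictor table (ULBT)
tmd.tp,40,0,published per-predictor table (TMD)
tmd.fp,19,0,published per-predictor table (TMD)
tmd.fn,42,0,published per-predictor table (TMD)
tmd.tn,99,0,published per-predictor table (TMD)
tmd.sensitivity_pct,48.78,2,published per-predictor table (TMD)
tmd.specificity_pct,83.90,2,published per-predictor table (TMD)
hmd.tp,39,0,published per-predictor table (HMD)
hmd.fp,17,0,published per-predictor table (HMD)
hmd.fn,43,0,published per-predictor table (HMD)
hmd.tn,101,0,published per-predictor table (HMD)
hmd.sensitivity_pct,47.56,2,published per-predictor table (HMD)
hmd.specificity_pct,85.59,2,published per-predictor table (HMD)
composite.tp,65,0,published composite 2x2
composite.fp,34,0,published composite 2x2
composite.fn,17,0,published composite 2x2
composite.tn,84,0,published composite 2x2
composite.sensitivity_pct,79.27,2,published results text
composite.specificity_pct,71.19,2,published results text
composite.ppv_pct,65.66,2,published results text
composite.npv_pct,83.17,2,published results text
composite.accuracy_pct,74.50,2,published results text
prevalence_pct,41,0,published incidence figure
agreement.mcnemar_chi2,5.67,2,published results text
agreement.mcnemar_p,0.017,3,published results text
agreement.kappa,0.489,3,published results text
agreement.cohens_g_marginal,0.085,3,published results text
roc.auc_binary,0.752,3,published results text
roc.auc_se,0.036,3,published results text
cutoff1.sensitivity_pct,79.3,1,published cutoff sweep
cutoff1.fpr_pct,28.8,1,published cutoff sweep
cutoff1.specificity_pct,71.2,1,published cutoff sweep
cutoff1.youden_pct,50.5,1,published cutoff sweep
cutoff2.sensitivity_pct,62.2,1,published cutoff sweep
cutoff2.fpr_pct,19.5,1,published cutoff sweep
cutoff2.specificity_pct,80.5,1,published cutoff sweep
cutoff2.youden_pct,42.7,1,published cutoff sweep
cutoff3.sensitivity_pct,36.6,1,published cutoff sweep
cutoff3.fpr_pct,3.4,1,published cutoff sweep
cutoff3.specificity_pct,96.6,1,published cutoff sweep
cutoff3.youden_pct,33.2,1,published cutoff sweep
cutoff4.sensitivity_pct,7.3,1,published cutoff sweep
cutoff4.fpr_pct,0.8,1,published cutoff sweep
cutoff4.specificity_pct,99.2,1,published cutoff sweep
cutoff4.youden_pct,6.5,1,published cutoff sweep
cutoff5.sensitivity_pct,0.0,1,published cutoff sweep
cutoff5.fpr_pct,0.0,1,published cutoff sweep
cutoff5.specificity_pct,100.0,1,published cutoff sweep
cutoff5.youden_pct,0.0,1,published cutoff sweep
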