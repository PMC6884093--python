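# Published analysis defaults: frozen composite clusters, PPMS+SPMS merged
# into PMS, race/age/sex adjustment with pairwise interactions, alpha 0.05.
# This file mirrors PipelineConfig(); load with PipelineConfig.from_yaml().
grouping:
  HD: HD
  RRMS: RRMS
  PPMS: PMS
  SPMS: PMS
covariates: [age, sex, race]
covariate_interactions: true
selection_alpha: 0.05
cluster_mode: frozen
derive_csf: false
r_threshold: 0.3
icc_flag_threshold: 0.8
alpha: 0.05
severity_cols: [msss, armss, msdss]
subcohorts: [MS, RRMS, PMS]
seed: 0
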