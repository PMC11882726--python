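# Packaged demo: nine synthetic cohorts shaped like the executive-function
# GWAS panel, desk-scale SNP count, full pipeline end to end.
mode: synthetic
outdir: factorgwas_demo
seed: 0
m_snps: 20000
overlap_rho: 0.25
n_blocks: 100
h2_z_threshold: 1.645
collinearity_r: 0.9
models: [zoo]
gwas_model: bifactor_wm_substitution
zdiff_threshold: 1.0
qsnp_alpha: 5.0e-8
gwas_max_snps: 200
p_sig: 5.0e-8
r2_indep: 0.6
r2_lead: 0.1
merge_window: 250000
r2_novel: 0.6
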