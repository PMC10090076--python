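# Registry of feature-spec variants (M1-M20).
#
# Each entry names the feature blocks a model variant uses. Entries whose
# exact composition is not fully determined carry
# `uncertain: true` and may be edited without touching code; the anchored
# entries (M5, M12, M13, M14, M15, M16, M20) are the ones the package's
# tests rely on.
#
# Block vocabulary:
#   drug_categorical, cell_line_categorical, chemical_structure,
#   cancer_gene_expression, monotherapy_ic50, monotherapy_ri,
#   drc_baseline, drc_imputation
# Optional per-spec config: imputation_methods (subset of linear/lagrange/ll4).

M1:
  blocks: [drc_baseline]
M2:
  blocks: [drc_imputation]
  imputation_methods: [linear]
M3:
  blocks: [drc_imputation]
  imputation_methods: [lagrange]
M4:
  blocks: [drc_imputation]
  imputation_methods: [ll4]
M5:
  blocks: [drc_imputation]
M6:
  blocks: [drc_baseline, drc_imputation]
  uncertain: true
M7:
  blocks: [monotherapy_ic50]
  uncertain: true
M8:
  blocks: [monotherapy_ri]
  uncertain: true
M9:
  blocks: [monotherapy_ic50, monotherapy_ri]
M10:
  blocks: [monotherapy_ic50, monotherapy_ri, drc_baseline]
  uncertain: true
M11:
  blocks: [monotherapy_ic50, monotherapy_ri, drc_imputation]
  uncertain: true
M12:
  blocks: [monotherapy_ic50, monotherapy_ri, drc_baseline, drc_imputation]
M13:
  blocks: [drug_categorical, cell_line_categorical]
M14:
  blocks: [drug_categorical, cell_line_categorical, chemical_structure,
           cancer_gene_expression]
M15:
  blocks: [drug_categorical, cell_line_categorical, chemical_structure,
           cancer_gene_expression, monotherapy_ic50, monotherapy_ri]
M16:
  blocks: [drug_categorical, cell_line_categorical, chemical_structure,
           cancer_gene_expression, monotherapy_ic50, monotherapy_ri,
           drc_baseline]
M17:
  blocks: [drug_categorical, cell_line_categorical, chemical_structure,
           cancer_gene_expression, monotherapy_ic50, monotherapy_ri,
           drc_imputation]
  imputation_methods: [linear]
  uncertain: true
M18:
  blocks: [drug_categorical, cell_line_categorical, chemical_structure,
           cancer_gene_expression, monotherapy_ic50, monotherapy_ri,
           drc_imputation]
  imputation_methods: [lagrange]
  uncertain: true
M19:
  blocks: [drug_categorical, cell_line_categorical, chemical_structure,
           cancer_gene_expression, monotherapy_ic50, monotherapy_ri,
           drc_imputation]
  imputation_methods: [ll4]
  uncertain: true
M20:
  blocks: [drug_categorical, cell_line_categorical, chemical_structure,
           cancer_gene_expression, monotherapy_ic50, monotherapy_ri,
           drc_imputation]
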