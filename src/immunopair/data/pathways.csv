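pathway,gene
leukocyte_functions,PTPRC
leukocyte_functions,ITGB2
leukocyte_functions,ITGAM
leukocyte_functions,S100A12
leukocyte_functions,FPR1
leukocyte_functions,LYZ
myeloid_differentiation_maintenance,CSF3R
myeloid_differentiation_maintenance,CSF1R
myeloid_differentiation_maintenance,MMP8
myeloid_differentiation_maintenance,LTF
myeloid_differentiation_maintenance,LCN2
myeloid_differentiation_maintenance,CEACAM8
myeloid_differentiation_maintenance,ITGB4
myeloid_differentiation_maintenance,FCN1
t_cell_functions,CD3D
t_cell_functions,CD3E
t_cell_functions,LCK
t_cell_functions,TRAC
t_cell_functions,GZMB
t_cell_functions,CD8A
b_cell_functions,CD19
b_cell_functions,MS4A1
b_cell_functions,CD79A
b_cell_functions,CD79B
b_cell_functions,CD22
nk_cell_functions,NKG7
nk_cell_functions,GNLY
nk_cell_functions,KLRD1
nk_cell_functions,NCR1
nk_cell_functions,GZMB
nk_cell_functions,KLRF1
mhc_class_ii_antigen_presentation,HLA-DPB1
mhc_class_ii_antigen_presentation,HLA-DRB3
mhc_class_ii_antigen_presentation,HLA-DRA
mhc_class_ii_antigen_presentation,HLA-DPA1
mhc_class_ii_antigen_presentation,HLA-DMB
mhc_class_ii_antigen_presentation,CD74
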