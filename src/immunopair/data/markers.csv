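cell_type,gene
T_cells,CD3D
T_cells,CD3E
T_cells,CD3G
T_cells,TRAC
T_cells,CD6
T_cells,LCK
CD4_T_cells,CD4
CD4_T_cells,CD40LG
CD4_T_cells,IL7R
CD8_T_cells,CD8A
CD8_T_cells,CD8B
CD8_T_cells,GZMK
gamma_delta_T_cells,TRDC
gamma_delta_T_cells,TRGC1
gamma_delta_T_cells,TRGV9
Tregs,FOXP3
Tregs,CTLA4
Tregs,IKZF2
B_cells,CD19
B_cells,MS4A1
B_cells,CD79A
B_cells,CD79B
B_cells,BLK
B_cells,CD22
plasma_B_cells,TNFRSF17
plasma_B_cells,MZB1
plasma_B_cells,JCHAIN
NK_cells,NCR1
NK_cells,KLRD1
NK_cells,NKG7
NK_cells,GNLY
NK_cells,KLRB1
NK_cells,KLRF1
neutrophils,FCGR3B
neutrophils,CEACAM8
neutrophils,CSF3R
neutrophils,S100A12
neutrophils,FPR1
neutrophils,MMP8
neutrophils,LTF
neutrophils,LCN2
monocytes,CD14
monocytes,LYZ
monocytes,FCN1
monocytes,VCAN
monocytes,CSF1R
monocytes,CD163
monocytes,ITGAM
dendritic_cells,CLEC4C
dendritic_cells,FLT3
dendritic_cells,CD1C
dendritic_cells,THBD
mast_cells,TPSAB1
mast_cells,CPA3
mast_cells,MS4A2
mast_cells,HDC
eosinophils,CLC
eosinophils,IL5RA
eosinophils,PRG2
eosinophils,EPX
eosinophils,SIGLEC8
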