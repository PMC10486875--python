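population,cell_type
T_cells,T_cells
CD4_T_cells,CD4_T_cells
CD8_T_cells,CD8_T_cells
gamma_delta_T_cells,gamma_delta_T_cells
B_cells,B_cells
NK_cells,NK_cells
mature_neutrophils,neutrophils
monocytes,monocytes
eosinophils,eosinophils
dendritic_cells,dendritic_cells
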