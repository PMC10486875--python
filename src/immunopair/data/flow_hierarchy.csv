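child,parent
mature_neutrophils,granulocytes
immature_neutrophils,granulocytes
eosinophils,granulocytes
classical_monocytes,monocytes
intermediate_monocytes,monocytes
non_classical_monocytes,monocytes
B_cells,lymphocytes
T_cells,lymphocytes
NK_cells,lymphocytes
CD4_T_cells,T_cells
CD8_T_cells,T_cells
gamma_delta_T_cells,T_cells
CD16_pos_NK_cells,NK_cells
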