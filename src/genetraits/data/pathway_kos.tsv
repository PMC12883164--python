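ko_id	pathway
K00360	nitrogen_assimilation
K00366	nitrogen_assimilation
K00367	nitrogen_assimilation
K00372	nitrogen_assimilation
K10534	nitrogen_assimilation
K17877	nitrogen_assimilation
K00260	nitrogen_assimilation
K00261	nitrogen_assimilation
K00262	nitrogen_assimilation
K00264	nitrogen_assimilation
K00265	nitrogen_assimilation
K00266	nitrogen_assimilation
K00284	nitrogen_assimilation
K01915	nitrogen_assimilation
K02575	nitrogen_assimilation
K15576	nitrogen_assimilation
K15577	nitrogen_assimilation
K15578	nitrogen_assimilation
K15579	nitrogen_assimilation
K00531	nitrogen_assimilation
K02586	nitrogen_assimilation
K02588	nitrogen_assimilation
K02591	nitrogen_assimilation
K22896	nitrogen_assimilation
K22897	nitrogen_assimilation
K22898	nitrogen_assimilation
K22899	nitrogen_assimilation
K03320	nitrogen_assimilation
K04751	nitrogen_assimilation
K04752	nitrogen_assimilation
K07708	nitrogen_assimilation
K07712	nitrogen_assimilation
K00990	nitrogen_assimilation
K19338	nitrogen_assimilation
K03719	nitrogen_assimilation
K00982	nitrogen_assimilation
K03092	nitrogen_assimilation
ko01200	carbon_metabolism
ko03010	ribosomal_proteins
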