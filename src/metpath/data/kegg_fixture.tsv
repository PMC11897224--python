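pathway_id	name	kegg_compound_id
hsa01200	Carbon metabolism	C00022
hsa01200	Carbon metabolism	C00025
hsa01200	Carbon metabolism	C00037
hsa01200	Carbon metabolism	C00041
hsa01200	Carbon metabolism	C00049
hsa01200	Carbon metabolism	C00064
hsa01200	Carbon metabolism	C00065
hsa01200	Carbon metabolism	C00042
hsa01200	Carbon metabolism	C00122
hsa01200	Carbon metabolism	C00149
hsa01200	Carbon metabolism	C00158
hsa01200	Carbon metabolism	C00311
hsa01200	Carbon metabolism	C00026
hsa01200	Carbon metabolism	C00186
hsa01200	Carbon metabolism	C00197
hsa01200	Carbon metabolism	C00074
hsa01200	Carbon metabolism	C00092
hsa00250	Alanine, aspartate and glutamate metabolism	C00025
hsa00250	Alanine, aspartate and glutamate metabolism	C00026
hsa00250	Alanine, aspartate and glutamate metabolism	C00041
hsa00250	Alanine, aspartate and glutamate metabolism	C00049
hsa00250	Alanine, aspartate and glutamate metabolism	C00064
hsa00250	Alanine, aspartate and glutamate metabolism	C00122
hsa00250	Alanine, aspartate and glutamate metabolism	C00042
hsa00250	Alanine, aspartate and glutamate metabolism	C00158
hsa00260	Glycine, serine and threonine metabolism	C00037
hsa00260	Glycine, serine and threonine metabolism	C00065
hsa00260	Glycine, serine and threonine metabolism	C00188
hsa00260	Glycine, serine and threonine metabolism	C00114
hsa00260	Glycine, serine and threonine metabolism	C00719
hsa00260	Glycine, serine and threonine metabolism	C00213
hsa00260	Glycine, serine and threonine metabolism	C00097
hsa00260	Glycine, serine and threonine metabolism	C00022
hsa00230	Purine metabolism	C00020
hsa00230	Purine metabolism	C00130
hsa00230	Purine metabolism	C00144
hsa00230	Purine metabolism	C00212
hsa00230	Purine metabolism	C00262
hsa00230	Purine metabolism	C00385
hsa00230	Purine metabolism	C00387
hsa00230	Purine metabolism	C00086
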