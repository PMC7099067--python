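node	region	species_pair	divergence_ma	contact_epoch	transition_category
A	W-France	H. meridionalis / H. arborea-molleri	20	Antiquity	no_gene_flow
B	S-Anatolia	H. orientalis / H. savignyi	8.8	>=LGM	steep
C	NE-Italy/Slovenia	H. arborea / H. perrini	6.6	>=LGM	steep
C	W-Switzerland	H. arborea / H. perrini	6.6	1950s	wide
D	Balkans	H. arborea / H. orientalis	5.1	>=LGM	steep
D	Poland	H. arborea / H. orientalis	5.1	post-glacial	wide
D	W-France	H. arborea / H. molleri	5.1	post-glacial	wide
E	Central Italy	H. perrini / H. intermedia	3.5	post-glacial	wide
F	Levant	H. savignyi / H. felixarabica	6.4	>=LGM	steep
G	E-Algeria	H. meridionalis / H. carthaginiensis	4.1	>=LGM	steep
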