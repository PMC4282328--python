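# Described extant insect (class Insecta) families and genera per order, from
# entomological literature estimates, alongside the counts represented in a
# curated genus-trained COI reference set mined from GenBank.  '?' marks
# orders with no published estimate of genus numbers.
order	families_described	families_represented	genera_described	genera_represented
Archaeognatha	2	2	64	9
Blattodea	17	12	738	72
Coleoptera	176	118	29500	1956
Dermaptera	11	4	182	5
Diptera	158	79	9323	739
Embioptera	11	6	84	9
Ephemeroptera	42	21	405	76
Grylloblattodea	1	1	5	1
Hemiptera	108	83	?	892
Hymenoptera	89	53	8359	728
Lepidoptera	131	110	15528	3362
Mantodea	14	8	436	56
Mantophasmatodea	2	2	10	5
Mecoptera	9	5	32	7
Megaloptera	2	2	33	5
Neuroptera	16	16	?	69
Odonata	31	13	642	57
Orthoptera	40	19	4418	243
Phasmatodea	13	9	454	63
Phthiraptera	15	7	50	10
Plecoptera	16	11	286	46
Psocoptera	40	2	320	2
Raphidioptera	2	2	18	4
Siphonaptera	16	3	246	6
Strepsiptera	8	4	?	6
Thysanoptera	9	3	767	44
Trichoptera	49	35	601	203
Zygentoma	3	3	117	4
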