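label	n	coi_intra	coi_inter	its_intra	its_inter	flags
Amanita flavoconia	2	0.0000	0.0930	0.0022	0.0511	bold=COI
Amanita porphyria	2	0.0000	0.1275	0.0000	CAPPED	bold=ITS
Boletus badius	2	0.0000	0.0439	0.0000	CAPPED	bold=ITS
Boletus edulis	9	0.0062	0.0020	0.0104	0.0497	bold=ITS;italic=COI
Boletus nobilissimus	4	0.0000	0.0020	0.0039	0.0223	bold=ITS
Boletus regineus	4	0.0041	0.0020	0.0142	0.0096	bold=ITS;italic=COI,ITS
Boletus rex-veris	2	0.0020	0.0020	0.0029	0.0308	bold=ITS;italic=COI
Boletus variipes	2	0.0000	0.0145	0.0048	0.0538	bold=COI
Catathelasma ventricosa	2	0.0000	0.1055	0.0043	CAPPED	bold=ITS
Clitocybe sp. (143Alg, 38Alg)	2	0.0000	0.0860	0.0091	CAPPED	bold=ITS
Collybia cirrhata	3	0.0000	0.0129	0.0000	0.0345	bold=COI
Entoloma clypeatum	2	0.0000	0.1276	0.0000	CAPPED	bold=ITS
Entoloma sinuatum	2	0.0000	0.0762	0.0028	CAPPED	bold=ITS
Entoloma sp. (parasite on Tricholoma focale)	2	0.0064	0.0417	0.0000	0.0390	bold=ITS
Hygrocybe conica	3	0.0000	0.0260	0.0329	CAPPED	bold=ITS
Hygrocybe lacmus	2	0.0000	0.1201	0.0083	CAPPED	bold=ITS
Hygrocybe miniata	2	0.0064	0.0238	0.0747	CAPPED	bold=ITS;may be two cryptic species
Hygrophorus agathiosmus	2	0.0043	0.0373	0.0000	CAPPED	bold=ITS
Hygrophorus flavodiscus	3	0.0000	0.0283	0.0025	CAPPED	bold=ITS
Hygrophorus pudorinus	3	0.0000	0.0554	0.0056	CAPPED	bold=ITS
"Inferiboletus"	2	0.0000	0.0335	0.0015	CAPPED	bold=ITS
Laccaria spp.	2	NA	0.0107	NA	0.0575
Lacrymaria/Psathyrella	2	NA	0.0394	NA	0.0837
Leccinum vulpinum	2	0.0000	0.0208	0.0050	CAPPED	bold=ITS;incomplete sequence present, only first 408 bp included
Lepiota castanea/Lepiota sp. 16JS06	2	NA	0.0305	NA	0.0313
Pholiota sp.	3	0.0000	0.1051	0.0000	CAPPED	bold=ITS
Pluteus sp.A	4	0.0021	0.0216	0.0000	0.0733	bold=COI
Pluteus sp.B	2	0.0000	0.0043	0.0000	0.0323	bold=ITS
Pluteus sp.C	2	0.0021	0.0043	0.0186	0.0258	bold=COI
Pluteus sp.D	2	0.0000	0.0173	0.0000	0.0258	bold=ITS
Pluteus sp.E	2	0.0000	0.0173	0.0067	0.0390	bold=COI
Psathyrella 72CAT06/151CAT06	2	NA	0.0693	NA	0.1207	incomplete sequence present, first 213 bp excluded
Psathyrella gracilis	2	0.0000	0.0786	0.0022	CAPPED	bold=ITS
Stropharia ambigua	4	0.0000	0.1432	0.0000	CAPPED	bold=ITS
Suillus cavipes	2	0.0000	0.0328	0.0000	0.0662	bold=ITS
Tricholoma inamoenum	3	0.0043	0.0260	0.0000	CAPPED	bold=ITS
Tricholoma sejunctum group	3	NA	0.0107	NA	0.1136
Xerocomus subtomentosus	2	0.0000	0.0271	0.0022	CAPPED	bold=ITS
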