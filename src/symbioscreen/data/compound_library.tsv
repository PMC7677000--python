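name	cas	formula	monoisotopic_mass	is_nutrient
Glutaric acid	110-94-1	C5H8O4	132.04226	0
Thymine	65-71-4	C5H6N2O2	126.04293	0
Ethylmalonic acid	601-75-2	C5H8O4	132.04226	0
Hypoxanthine	68-94-0	C5H4N4O	136.03851	0
Kynurenic acid	492-27-3	C10H7NO3	189.04259	0
Picolinic acid	98-98-6	C6H5NO2	123.03203	0
Ketoisocaproic acid	816-66-0	C6H10O3	130.06299	0
Phenyllactic acid	828-01-3	C9H10O3	166.06299	0
Adipic acid	124-04-9	C6H10O4	146.05791	0
Indoleacetic acid	87-51-4	C10H9NO2	175.06333	0
L-Tyrosine	60-18-4	C9H11NO3	181.07389	1
L-Sorbose	87-79-6	C6H12O6	180.06339	1
L-Leucine	61-90-5	C6H13NO2	131.09463	1
L-Valine	72-18-4	C5H11NO2	117.07898	1
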