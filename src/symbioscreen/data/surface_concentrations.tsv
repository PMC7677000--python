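metabolite	cas	group	mean_mg_per_l	detected
Adipic acid	124-04-9	nonaxenic	587.5	1
Indoleacetic acid	87-51-4	nonaxenic	191.2	1
Glutaric acid	110-94-1	nonaxenic	63.7	1
Ketoisocaproic acid	816-66-0	nonaxenic	66.1	1
Phenyllactic acid	828-01-3	nonaxenic	6.3	1
Kynurenic acid	492-27-3	nonaxenic	0.1	1
Picolinic acid	98-98-6	nonaxenic	0.18	1
Ethylmalonic acid	601-75-2	nonaxenic	0.0	1
Hypoxanthine	68-94-0	nonaxenic	0.001	1
Thymine	65-71-4	nonaxenic	NA	0
Adipic acid	124-04-9	axenic	2.4	1
Indoleacetic acid	87-51-4	axenic	11.9	1
Glutaric acid	110-94-1	axenic	8.7	1
Ketoisocaproic acid	816-66-0	axenic	4.9	1
Phenyllactic acid	828-01-3	axenic	14.0	1
Kynurenic acid	492-27-3	axenic	0.54	1
Picolinic acid	98-98-6	axenic	0.21	1
Ethylmalonic acid	601-75-2	axenic	0.01	1
Hypoxanthine	68-94-0	axenic	0.0	1
Thymine	65-71-4	axenic	NA	0
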