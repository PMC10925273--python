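# Printed sugar-binding dissociation constants of MelB variants measured by
# isothermal titration calorimetry, paired as (without, with) the condition
# whose cooperativity fold is reported: fold = kd_without / kd_with.
protein	ligand	kd_without	kd_without_err	condition_without	kd_with	kd_with_err	condition_with	unit	printed_fold
WT	melibiose	9.28	0.23	pH 7.5, no Na+	1.09	0.06	pH 7.5, 100 mM Na+	mM	8.51
D55C	melibiose	5.82	0.46	pH 7.5, no Na+	5.09	0.15	pH 7.5, 100 mM Na+	mM	1.14
WT	a-NPG	43.20	0.62	pH 7.5, no Na+	25.69	4.42	pH 7.5, 100 mM Na+	uM	1.68
D55C	a-NPG	15.06	1.86	pH 7.5, no Na+	13.54	1.38	pH 7.5, 100 mM Na+	uM	1.11
WT	melibiose	8.50	0.21	pH 8.5, no Na+	6.19	0.59	pH 6.25, no Na+	mM	1.37
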