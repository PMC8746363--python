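# Heavy-atom type parameters for the two-body interface score.
# lj_radius [A], lj_welldepth [kcal/mol], lk_dgfree [kcal/mol],
# lk_lambda [A], lk_volume [A^3]; donor/acceptor are hydrogen-bond flags.
# Values are this package's own parameterization; term semantics follow
# modern all-atom score functions; no numerical equivalence with any
# external implementation is claimed.
type	lj_radius	lj_welldepth	lk_dgfree	lk_lambda	lk_volume	donor	acceptor
CAbb	2.01	0.063	2.3	3.5	12.1	0	0
CObb	1.92	0.141	1.4	3.5	13.2	0	0
CH0	2.01	0.056	1.1	3.5	8.9	0	0
CH1	2.01	0.056	1.6	3.5	10.7	0	0
CH2	2.01	0.063	1.9	3.5	18.3	0	0
CH3	2.01	0.063	2.3	3.5	25.9	0	0
aroC	2.00	0.068	1.8	3.5	16.7	0	0
Nbb	1.75	0.161	-7.9	3.5	15.3	1	0
Ntrp	1.75	0.161	-8.9	3.5	9.5	1	0
Nhis	1.75	0.161	-9.7	3.5	9.3	0	1
NH2O	1.75	0.161	-7.8	3.5	15.7	1	0
Nlys	1.80	0.162	-16.3	3.5	16.5	1	0
Narg	1.75	0.161	-9.0	3.5	15.7	1	0
Npro	1.75	0.161	-1.6	3.5	3.7	0	0
OCbb	1.55	0.142	-8.0	3.5	12.3	0	1
OH	1.54	0.160	-6.7	3.5	10.8	1	1
ONH2	1.55	0.160	-7.0	3.5	10.1	0	1
OOC	1.49	0.210	-9.2	3.5	10.1	0	1
S	1.88	0.433	-1.7	3.5	17.6	0	0
SH1	1.88	0.433	1.9	3.5	23.2	0	0
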