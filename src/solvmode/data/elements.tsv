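# symbol	mass_amu	covalent_radius_angstrom	vdw_radius_angstrom
# covalent radii: Cordero 2008 single-bond values (low-spin for Mn/Fe/Co);
# vdW radii: Bondi/Mantina consensus, Alvarez for elements missing there;
# masses: standard atomic weights (abridged)
H	1.008	0.31	1.10
He	4.0026	0.28	1.40
Li	6.94	1.28	1.81
Be	9.0122	0.96	1.53
B	10.81	0.84	1.92
C	12.011	0.76	1.70
N	14.007	0.71	1.55
O	15.999	0.66	1.52
F	18.998	0.57	1.47
Ne	20.180	0.58	1.54
Na	22.990	1.66	2.27
Mg	24.305	1.41	1.73
Al	26.982	1.21	1.84
Si	28.085	1.11	2.10
P	30.974	1.07	1.80
S	32.06	1.05	1.80
Cl	35.45	1.02	1.75
Ar	39.948	1.06	1.88
K	39.098	2.03	2.75
Ca	40.078	1.76	2.31
Sc	44.956	1.70	2.15
Ti	47.867	1.60	2.11
V	50.942	1.53	2.07
Cr	51.996	1.39	2.06
Mn	54.938	1.39	2.05
Fe	55.845	1.32	2.04
Co	58.933	1.26	2.00
Ni	58.693	1.24	1.97
Cu	63.546	1.32	1.96
Zn	65.38	1.22	2.01
Ga	69.723	1.22	1.87
Ge	72.630	1.20	2.11
As	74.922	1.19	1.85
Se	78.971	1.20	1.90
Br	79.904	1.20	1.85
Kr	83.798	1.16	2.02
Rb	85.468	2.20	3.03
Sr	87.62	1.95	2.49
Y	88.906	1.90	2.32
Zr	91.224	1.75	2.23
Nb	92.906	1.64	2.18
Mo	95.95	1.54	2.17
Tc	98	1.47	2.16
Ru	101.07	1.46	2.13
Rh	102.91	1.42	2.10
Pd	106.42	1.39	2.10
Ag	107.87	1.45	2.11
Cd	112.41	1.44	2.18
In	114.82	1.42	1.93
Sn	118.71	1.39	2.17
Sb	121.76	1.39	2.06
Te	127.60	1.38	2.06
I	126.90	1.39	1.98
Xe	131.29	1.40	2.16
Cs	132.91	2.44	3.43
Ba	137.33	2.15	2.68
La	138.91	2.07	2.43
Ce	140.12	2.04	2.42
Pr	140.91	2.03	2.40
Nd	144.24	2.01	2.39
Pm	145	1.99	2.38
Sm	150.36	1.98	2.36
Eu	151.96	1.98	2.35
Gd	157.25	1.96	2.34
Tb	158.93	1.94	2.33
Dy	162.50	1.92	2.31
Ho	164.93	1.92	2.30
Er	167.26	1.89	2.29
Tm	168.93	1.90	2.27
Yb	173.05	1.87	2.26
Lu	174.97	1.87	2.24
Hf	178.49	1.75	2.23
Ta	180.95	1.70	2.22
W	183.84	1.62	2.18
Re	186.21	1.51	2.16
Os	190.23	1.44	2.16
Ir	192.22	1.41	2.13
Pt	195.08	1.36	2.13
Au	196.97	1.36	2.14
Hg	200.59	1.32	2.23
Tl	204.38	1.45	1.96
Pb	207.2	1.46	2.02
Bi	208.98	1.48	2.07
Po	209	1.40	1.97
At	210	1.50	2.02
Rn	222	1.50	2.20
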