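# Reaction scheme for the aerated cell-water radiolysis model, 25 C.
# Rate constants k in M^-1 s^-1 (bimolecular) or s^-1 (unimolecular).
# Reactions labelled (1)-(7)/R1-R42 form the cell-chemistry set; W1-W15 is the
# pure-water radiolysis core (standard low-LET literature constants, provenance
# "water-core"). HO2. is folded into O2.- (pKa 4.8, medium buffered at pH 7);
# H+ co-substrates are implicit (implicit_protons column, buffered pool).
#
# [species] columns: name, charge, diffusion coefficient (m^2/s, "-" = terminal
# sink, never a reactant), category.
[species]
e_aq	-1	4.9e-09	primary_radiolytic
OH_r	0	2.2e-09	primary_radiolytic
H_r	0	7.0e-09	primary_radiolytic
H2	0	4.8e-09	primary_radiolytic
H2O2	0	2.3e-09	primary_radiolytic
H3O_p	1	9.46e-09	primary_radiolytic
OH_m	-1	5.3e-09	primary_radiolytic
O2	0	2.4e-09	cellular_solute
RH	0	1.0e-10	cellular_solute
GSH	0	5.4e-10	cellular_solute
AH_m	-1	5.4e-10	cellular_solute
NO_r	0	2.2e-09	cellular_solute
TOH	0	4.0e-10	cellular_solute
O2_rm	-1	1.75e-09	product
R_r	0	1.0e-10	product
ROO_r	0	1.0e-10	product
RO_r	0	1.0e-10	product
ROOH	0	1.0e-10	product
GS_r	0	5.4e-10	product
GSOO_r	0	5.0e-10	product
GSSG	0	4.0e-10	product
GSSG_rm	-1	4.0e-10	product
GSSG_rp	1	4.0e-10	product
GSNO	0	5.0e-10	product
A_rm	-1	5.4e-10	product
TO_r	0	4.0e-10	product
RH_em	-1	-	product
RHH_r	0	-	product
R_R	0	-	product
ROOR	0	-	product
ROOOOR	0	-	product
ROH	0	-	product
ROONO	0	-	product
RNO	0	-	product
ONOO_m	-1	-	product
HNO2	0	-	product
GSOH	0	-	product
GSO_r	0	-	product
G_r	0	-	product
H2S	0	-	product
GSSG_2p	2	-	product
A	0	-	product
#
# [reactions] columns: label, reactant1, reactant2 ("-" = unimolecular),
# products ("+"-joined, "-" = none tracked), k, kinetic_class,
# implicit_protons (H+ consumed; negative = released), provenance.
[reactions]
R1	RH	e_aq	RH_em	1.5e9	diffusion_influenced	0	table1
R2	RH	H_r	RHH_r	8e7	activation_controlled	0	table1
R3	O2	e_aq	O2_rm	1.9e10	diffusion_influenced	0	table1
R4	O2	H_r	O2_rm	2.1e10	diffusion_influenced	-1	table1
R5	O2_rm	O2_rm	O2+H2O2	4e9	diffusion_influenced	2	table1
R6	H2O2	H2O2	O2	2e7	activation_controlled	0	table1
(1)	RH	OH_r	R_r	5e8	activation_controlled	0	table1
(2)	R_r	O2	ROO_r	2e9	diffusion_influenced	0	table1
R7	R_r	R_r	R_R	1e8	activation_controlled	0	table1
R8	R_r	ROO_r	ROOR	5e7	activation_controlled	0	table1
R9	ROO_r	ROO_r	ROOOOR	1e5	activation_controlled	0	table1
R10	ROO_r	RH	ROOH+R_r	1.3e3	activation_controlled	0	table1
R11	ROO_r	O2_rm	ROOH+O2	5e7	activation_controlled	1	table1
R12	e_aq	ROOH	RO_r+OH_m	1e10	diffusion_influenced	0	table1
R13	RO_r	RH	ROH+R_r	5e4	activation_controlled	0	table1
(5)	ROO_r	GSH	GS_r+ROOH	5e4	activation_controlled	0	table1
R14	R_r	GSH	GS_r+RH	5.6e6	activation_controlled	0	table1
R15	GSH	e_aq	G_r+H2S	4.5e9	diffusion_influenced	1	table1
R16	GSH	H_r	GS_r+H2	1.8e9	diffusion_influenced	0	table1
R17	GSH	OH_r	GS_r	1.4e10	diffusion_influenced	0	table1
R18	GS_r	O2	GSOO_r	2e9	diffusion_influenced	0	table1
R19	GSOO_r	-	GS_r+O2	6.2e5	activation_controlled	0	table1
R20	GSOO_r	GSH	GSO_r+GSOH	2e6	activation_controlled	0	table1
R21	GS_r	GS_r	GSSG	7.5e8	activation_controlled	0	table1
R22	GS_r	GSH	GSSG_rm	3.5e8	activation_controlled	-1	table1
R23	GSSG_rm	O2	GSSG+O2_rm	5.1e8	activation_controlled	0	table1
R24	GSSG	e_aq	GSSG_rm	3.7e9	diffusion_influenced	0	table1
R25	GSSG	H_r	GSH+GS_r	1e10	diffusion_influenced	0	table1
R26	GSSG	OH_r	GSSG_rp+OH_m	1.7e10	diffusion_influenced	0	table1
R27	GSSG_rp	GSSG_rp	GSSG_2p+GSSG	2.5e9	diffusion_influenced	0	table1
R28	GS_r	NO_r	GSNO	3e9	diffusion_influenced	0	table1
R29	GS_r	GSNO	GSSG+NO_r	1.7e9	diffusion_influenced	0	table1
R30	GS_r	AH_m	GSH+A_rm	6e8	activation_controlled	0	table1
R31	R_r	AH_m	RH+A_rm	1e7	activation_controlled	0	table1
(7)	ROO_r	AH_m	ROOH+A_rm	2.2e6	activation_controlled	0	table1
R32	RO_r	AH_m	ROH+A_rm	1.6e9	diffusion_influenced	0	table1
R33	AH_m	O2_rm	A_rm+H2O2	2.7e5	activation_controlled	1	table1
R34	AH_m	OH_r	A_rm	1.1e10	diffusion_influenced	0	table1
R35	A_rm	A_rm	AH_m+A	2.8e5	activation_controlled	1	table1
R36	A_rm	O2_rm	A+H2O2	2.6e8	activation_controlled	2	table1
R37	OH_r	TOH	TO_r	1e10	diffusion_influenced	0	table1
R38	R_r	TOH	RH+TO_r	2.5e6	activation_controlled	0	table1
R39	ROO_r	TOH	ROOH+TO_r	5e5	activation_controlled	0	table1
R40	TO_r	AH_m	TOH+A_rm	1.3e7	activation_controlled	0	table1
(3)	NO_r	O2_rm	ONOO_m	1.9e10	diffusion_influenced	0	table1
R41	NO_r	OH_r	HNO2	1e10	diffusion_influenced	0	table1
R42	R_r	NO_r	RNO	2e9	diffusion_influenced	0	table1
(4)	ROO_r	NO_r	ROONO	2e9	diffusion_influenced	0	table1
W1	e_aq	OH_r	OH_m	3.0e10	diffusion_influenced	0	water-core
W2	e_aq	H2O2	OH_r+OH_m	1.1e10	diffusion_influenced	0	water-core
W3	e_aq	H3O_p	H_r	2.3e10	diffusion_influenced	0	water-core
W4	e_aq	e_aq	H2+OH_m+OH_m	5.5e9	diffusion_influenced	0	water-core
W5	e_aq	H_r	H2+OH_m	2.5e10	diffusion_influenced	0	water-core
W6	e_aq	O2_rm	H2O2+OH_m+OH_m	1.3e10	diffusion_influenced	0	water-core
W7	OH_r	OH_r	H2O2	5.5e9	diffusion_influenced	0	water-core
W8	OH_r	H2	H_r	4.2e7	activation_controlled	0	water-core
W9	OH_r	H2O2	O2_rm	2.7e7	activation_controlled	-1	water-core
W10	OH_r	O2_rm	O2+OH_m	8e9	diffusion_influenced	0	water-core
W11	H_r	H_r	H2	7.8e9	diffusion_influenced	0	water-core
W12	H_r	H2O2	OH_r	9.0e7	activation_controlled	0	water-core
W13	H_r	OH_r	-	7.0e9	diffusion_influenced	0	water-core
W14	H3O_p	OH_m	-	1.1e11	diffusion_influenced	0	water-core
W15	H_r	OH_m	e_aq	2.2e7	activation_controlled	0	water-core
#
# [moieties] columns: moiety name, comma-joined species=count pairs. Every
# reaction must conserve every moiety (stoichiometry dot count = 0).
[moieties]
glutathione	GSH=1,GS_r=1,GSOO_r=1,GSO_r=1,GSOH=1,GSNO=1,G_r=1,GSSG=2,GSSG_rm=2,GSSG_rp=2,GSSG_2p=2
ascorbate	AH_m=1,A_rm=1,A=1
r_carbon	RH=1,R_r=1,ROO_r=1,RO_r=1,ROOH=1,ROH=1,ROONO=1,RNO=1,RH_em=1,RHH_r=1,R_R=2,ROOR=2,ROOOOR=2
no_nitrogen	NO_r=1,ROONO=1,RNO=1,ONOO_m=1,HNO2=1,GSNO=1
tocopherol	TOH=1,TO_r=1
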