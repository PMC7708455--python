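gene	role	target_type	default_sign
MOGS	glucosidase I	high_mannose	1
GANAB	glucosidase II alpha	high_mannose	1
PRKCSH	glucosidase II beta	high_mannose	1
MAN1A1	ER/Golgi alpha-1,2-mannosidase	high_mannose	-1
MAN1B1	ER alpha-1,2-mannosidase	high_mannose	0
MAN2A1	Golgi alpha-mannosidase II	high_mannose	0
DDOST	OST complex subunit	all	0
RPN1	OST complex subunit	all	0
RPN2	OST complex subunit	all	0
TUSC3	OST complex subunit	sialylated	0
STT3A	OST catalytic subunit	all	0
STT3B	OST catalytic subunit	all	0
FUT8	core fucosyltransferase	fucosylated	0
FUT11	fucosyltransferase	fucosylated	1
FUCA1	tissue alpha-L-fucosidase	fucosylated	-1
FUCA2	plasma alpha-L-fucosidase	fucosylated	-1
ST3GAL1	alpha-2,3-sialyltransferase	sialylated	1
ST6GAL1	alpha-2,6-sialyltransferase	sialylated	0
ST6GALNAC1	GalNAc alpha-2,6-sialyltransferase	sialylated	1
MGAT1	GlcNAc-transferase I	complex	0
MGAT5	GlcNAc-transferase V	complex	0
B4GALT1	beta-1,4-galactosyltransferase	complex	0
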