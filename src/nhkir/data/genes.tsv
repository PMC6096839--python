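species	designation	previous_designations	lineage
Mamu	Mamu-KIR1D	KIR1D|Mamu-KIR1D	III
Mamu	Mamu-KIR2DL04	2DL501NK|2DL503NK|KIR2DL4|KIR2DL4.1|MmKIR2DL4	I
Mamu	Mamu-KIR3DL01	2DL426NK|3DL34|KIR3DL|KIR3DL-like_1|KIR3DL1|KIR3DL1-like1|KIR3DL12|KIR3DL13|KIR3DL14|KIR3DL15|KIR3DL19|KIR3DL1_variant_2|KIR3DL2|KIR3DL2-old|KIR3DL3|KIR3DL4|KIR3DL5	II
Mamu	Mamu-KIR3DL02	KIR3DL-like_3|KIR3DL2|KIR3DL21|KIR3DL21-like1	II
Mamu	Mamu-KIR3DL04	KIR3DL11	II
Mamu	Mamu-KIR3DL05	3DL7b-3DL40|KIR3DL|KIR3DL-3|KIR3DL16|KIR3DL7|KIR3DL7-like2|KIR3DL07	II
Mamu	Mamu-KIR3DL06	KIR3DL6	II
Mamu	Mamu-KIR3DL07	2DL420|KIR3DL|KIR3DL18|KIR3DL7|KIR3DL7-like1|KIR3DL7-like3|KIR3DL03	II
Mamu	Mamu-KIR3DL08	KIR3DL|KIR3DL-like_2|KIR3DL17|KIR3DL8|KIRDL8|Mamu-KIR3DL04|Mamu-KIR3DL4	II
Mamu	Mamu-KIR3DL10	3DL10-2DL501|3DL3NK|KIR3DL|KIR3DL10|KIR3DL9|Mamu-KIR3DL05	II
Mamu	Mamu-KIR3DL11	KIR3DL|KIR3DL-1|KIR3DL-6|KIR3DL-7|KIR3DL11	II
Mamu	Mamu-KIR3DL20	KIR3DL20|KIR3DL20_variant_2|KIR3DL06|KIR2DL5	V
Mamu	Mamu-KIR3DLW03	KIR3DL-4|KIR3DL-5|KIR3DL-like1-BNB|KIR3DL21	II
Mamu	Mamu-KIR3DLX1	KIR3DL0	X-divergent
Mamu	Mamu-KIR3DS01	KIR3DH-7|KIR3DH1|KIR3DH5|Mamu-KIR3DS01-JHB-HEFGH	II
Mamu	Mamu-KIR3DS02	3DH2|3DH42|KIR3DH-like_5|KIR3DH-like_6|KIR3DH10|KIR3DH12|KIR3DH13|KIR3DH14|KIR3DH15|KIR3DH16|KIR3DH2	II
Mamu	Mamu-KIR3DS03	KIR3DH3|KIR3DH8|KIR3DH9	II
Mamu	Mamu-KIR3DS04	KIR3DH-1|KIR3DH4|KIR3DH6	II
Mamu	Mamu-KIR3DS05	KIR3DH1|KIR3DM-1|KIR3DM1|KIR3DM6|KIR_Partial_Sequence_1	II
Mamu	Mamu-KIR3DS06	KIR3DH-4|KIR3DH-like8|KIR3DH-like_7|KIR3DH18	II
Mamu	Mamu-KIR3DSW07	KIR3DH-5|KIR3DH7|Mamu-KIR3DS07-JHB-HO	II
Mamu	Mamu-KIR3DSW08	KIR3DH-2|KIR3DH-3|KIR3DH-4|KIR3DH-5|KIR3DH-like_1|KIR3DH-like_2|KIR3DH-like_3|KIR3DH-like_4|KIR3DH21|KIR3DSW08	II
Mamu	Mamu-KIR3DSW09	KIR3DH-8|KIR3DH20|KIR3DH5|KIR3DH5-like1|mmKIR3DH-1	II
Patr	Patr-KIR2DL4		I
Patr	Patr-KIR2DL5
Patr	Patr-KIR2DL6	Pt-NewII
Patr	Patr-KIR2DL7
Patr	Patr-KIR2DL8	Pt-NewIII
Patr	Patr-KIR2DL9
Patr	Patr-KIR2DS4
Patr	Patr-KIR3DL1	Pt-KIR3DL1/2|Pt-KIR3DL3|Pt-KIR3DL1|Pt-KIR3DL2	II
Patr	Patr-KIR3DL3	Patr-KIRC1|Pt-NewI	II
Patr	Patr-KIR3DL4
Patr	Patr-KIR3DL5
Patr	Patr-KIR3DS2
Patr	Patr-KIR3DS6	Pt-KIR3DL6
Poab	Poab-KIR2DL10	Popy-KIR2DL10|2DLA
Poab	Poab-KIR2DL11	Popy-KIR2DL11|2DLB
Poab	Poab-KIR2DL12	Popy-KIR2DL11|2DLC
Poab	Poab-KIR2DL5	Popy-KIR2DL5|2DL5
Poab	Poab-KIR2DS10	2DSD/2DSA
Poab	Poab-KIR2DS13	Popy-KIR2DS13|2DSC1/2DSB
Poab	Poab-KIR2DS14	Popy-KIR2DS14|2DSB/2DSD2|2DSA/2DSD1
Poab	Poab-KIR3DL1	Popy-KIR3DL1|3DLH|3DLC|3DLD2|3DLD1|3DLA|3DLI|3DLB	II
Poab	Poab-KIR3DL3	Popy-KIR3DL3|3DL3	II
Poab	Poab-KIR3DS1	Popy-KIR3DS1|3DS1
Poab	Poab-KIRDP	Popy-KIRDP|DP
Popy	Popy-KIR2DL11	Popy-KIR2DLB
Popy	Popy-KIR2DL12	Popy-KIR2DLC
Popy	Popy-KIR2DL5
Popy	Popy-KIR2DS10	Popy-KIR2DSD/2DSA
Popy	Popy-KIR2DS13	Popy-KIR2DSC2/2DSB
Popy	Popy-KIR2DS14	Popy-KIR2DSB/2DSD2|2DSA/2DSD1
Popy	Popy-KIR2DS15
Popy	Popy-KIR3DL1	Popy-KIR3DL1|3DLF|3DLE2|3DLE1	II
Popy	Popy-KIR3DL3	Popy-KIR3DL3|3DL3	II
Popy	Popy-KIR3DS1	Popy-KIR3DS1|3DS1
Popy	Popy-KIRDP	Popy-KIRDP|DP
Bota	Bota-KIR2DL1
Bota	Bota-KIR2DS1
Bota	Bota-KIR2DS2
Bota	Bota-KIR2DS3
Bota	Bota-KIR2DXS1		X
Bota	Bota-KIR2DXP1		X
Bota	Bota-KIR2DXP2		X
Bota	Bota-KIR3DXL1	KIR3DL1	X
Bota	Bota-KIR3DXL2		X
Bota	Bota-KIR3DXL3		X
Bota	Bota-KIR3DXL4	KIR3DL2	X
Bota	Bota-KIR3DXL5		X
Bota	Bota-KIR3DXL6	KIR3DL1P|KIR3DL3	X
Bota	Bota-KIR3DXL7		X
Bota	Bota-KIR3DXS1	KIR3DS1	X
Bota	Bota-KIR3DXS2		X
Bota	Bota-KIR3DXS3		X
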