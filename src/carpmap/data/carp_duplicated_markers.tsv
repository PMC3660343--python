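marker_id	lg_id	orthologous_chromosome
CAFS1255-1	LG16	chr1
CAFS1255-2	LG3	chr1
CAFS3868-1	LG3	chr1
CAFS3868-2	LG16	chr1
CAFS2910-1	LG19	chr11
CAFS2910-2	LG50	chr11
CAFS642-1	LG36	chr13
CAFS642-2	LG43	chr13
CAFS3267-1	LG36	chr13
CAFS3267-2	LG43	chr13
CAFS3617-1	LG8	chr15
CAFS3617-2	LG9	chr15
CAFS3169-1	LG8	chr15
CAFS3169-2	LG8	chr15
CAFS2152-1	LG29	chr18
CAFS2152-2	LG7	chr18
CAFS3097-1	LG7	chr18
CAFS3097-2	LG29	chr18
CAFS1913-1	LG32	chr22
CAFS1913-2	LG32	chr22
CAFS2444-1	LG11	chr3
CAFS2444-2	LG11	chr3
CAFS671-1	LG30	chr7
CAFS671-2	LG30	chr7
CAFS3906-1	LG38	chr8
CAFS3906-2	LG38	chr8
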