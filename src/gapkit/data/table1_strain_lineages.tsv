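organism	amoA_lineage	rrna_lineage
Nitrosospira multiformis Nsp16	D1	S3a
Nitrosospira sp. Nsp18	D1	S3a
Nitrosospira sp. Nsp11	D1	S3a
Nitrosospira briensis C-128	D2	S3b
Nitrosospira sp. Nsp1	D2	S3b
Nitrosospira sp. NRS527	D2	S3b
Nitrosospira sp. Nsp40	D3	S3b
Nitrosospira sp. Nsp22	D4	S3b
Nitrosospira tenuis Nv12	D5	S3c
Nitrosospira sp. Nv6	D5	S3c
Nitrosospira sp. Nsp37	D5	S3c
Nitrosospira sp. Nv4	D5	S3c
Nitrosospira sp. Nsp62	D6	S3d
Nitrosospira briensis Nsp10	D7	S3e
Nitrosospira briensis Nsp8	D7	S3e
Nitrosospira sp. Nsp14	D8	S3f
Nitrosospira sp. Nsp17	D8	S3f
Nitrosospira sp. Nsp2	D8	S3g
Nitrosospira sp. Nsp44	D8	S3h
Nitrosospira multiformis 24C	D9	S3i
Nitrosospira sp. L115	D9	S3i
Nitrosospira sp. A16	D9	S3i
Nitrosospira sp. AF	D9	S3i
Nitrosospira tenuis Nv1	D10	S3i
Nitrosospira multiformis ATCC 25196	D11	S3k
Nitrosospira multiformis Nl13	D11	S3k
Nitrosospira multiformis Nl4	D11	S3k
Nitrosospira multiformis Nl18	D11	S3k
Nitrosospira multiformis Nl15	D11	S3k
Nitrosospira multiformis Nl14	D11	S3k
Nitrosospira multiformis Nl7	D11	S3k
Nitrosospira multiformis Nl8	D11	S3k
Nitrosospira multiformis Nl12	D11	S3l
Nitrosospira multiformis Nl2	D11	S3m
Nitrosospira multiformis Nl3	D11	S3n
Nitrosospira sp. Nsp65	D12	S65
Nitrosospira sp. 56-18	D12	S65
Nitrosospira sp. Nsp5	D13	S0
Nitrosospira multiformis Nl1	D13	S0
Nitrosospira sp. Nsp13	D13	S0
Nitrosospira sp. Nsp6	D13	S0
Nitrosospira sp. Nsp12	D13	S0
Nitrosospira sp. 40KI	D13	S0
Nitrosospira sp. NpAV	D14	S0
Nitrosospira lacus APG3	D16	S0
Nitrosospira sp. Ka4	D16	S4
Nitrosospira sp. Ka3	D16	S4
Nitrosospira sp. Nsp41	D16	S3p
Nitrosospira sp. Nsp58	D16	S57
Nitrosospira sp. B6	D16	S2
Nitrosospira sp. III7	D15	S2
Nitrosospira sp. O13	D15	S2
Nitrosospira sp. O4	D15	S2
Nitrosospira sp. AHB1	D15	S2
Nitrosospira sp. Nsp57	D17	S57
Nitrosospira sp. Nl5	D17	S57
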