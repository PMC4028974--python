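mirna	fold	mir2disease	sum_degree
hsa-miR-1	8.53	No	1330
hsa-miR-21	0.26	Yes	1302
hsa-miR-124	9.48	No	1242
hsa-miR-34a	1850.82	Yes	1208
hsa-miR-125b	0.00	Yes	1194
hsa-miR-19a	0.09	No	701
hsa-miR-22	2.67	Yes	565
hsa-miR-146a	0.26	Yes	504
hsa-miR-153	240.02	No	451
hsa-miR-20b	0.06	No	432
hsa-miR-15b	0.08	No	411
hsa-miR-100	0.21	Yes	354
hsa-miR-29c	2.75	No	339
hsa-miR-9	9.56	No	338
hsa-miR-181b	0.41	Yes	328
hsa-miR-99a	6.08	Yes	311
hsa-miR-31	0.32	Yes	305
hsa-let-7a	0.48	Yes	267
hsa-miR-27b	0.46	Yes	263
hsa-miR-7	2.38	No	263
hsa-miR-296-5p	0.31	No	260
hsa-miR-27a	0.30	Yes	234
hsa-miR-185	0.21	No	230
hsa-miR-133a	92.91	No	211
hsa-miR-181c	4.72	No	172
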