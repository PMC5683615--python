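entry_id	thvp1	tavp1b	gi	ss	grain_color	glume_color	awns	threshability
12	ThVp-1d	Vp-1Ba	0.69	0.56	light red	white	absent	easy
33	ThVp-1c	Vp-1Ba	0.94	0.48	light red	white	present	easy
49	ThVp-1a	Vp-1Ba	0.81	0.51	light red	white	absent	easy
90	ThVp-1b	Vp-1Bc	0.74	0.58	light red	white	present	easy
166	ThVp-1a	Vp-1Ba	0.71	0.33	dark red	white	absent	easy
168	ThVp-1b	Vp-1Bc	0.62	0.51	dark red	red	absent	easy
186	ThVp-1a	Vp-1Ba	0.85	0.52	light red	white	absent	easy
192	ThVp-1a	Vp-1Ba	0.91	0.55	light red	white	absent	easy
237	ThVp-1c	Vp-1Ba	0.89	0.5	light red	white	present	hard
243	ThVp-1c	Vp-1Ba	0.68	0.45	light red	white	absent	easy
249	ThVp-1c	Vp-1Ba	0.73	0.61	dark red	white	present	easy
548	ThVp-1d	Vp-1Ba	0.75	0.66	light red	red	absent	easy
1375	ThVp-1d	hg	0.78	0.42	dark red	white	absent	hard
1382	ThVp-1a	Vp-1Ba	0.86	0.36	light red	white	absent	easy
1451	ThVp-1c	Vp-1Bc	0.87	0.01	blue	white	absent	hard
1512	ThVp-1b	Vp-1Bc	0.64	0.49	light red	red	absent	easy
1514	ThVp-1d	Vp-1Bc	0.95	0.5	dark red	red	absent	easy
1533	ThVp-1a	Vp-1Ba	0.54	0.04	dark red	white	absent	easy
1546	ThVp-1c	hg	0.77	0.54	light red	white	absent	easy
1626	ThVp-1d	Vp-1Ba	0.76	0.41	light red	red	absent	easy
1646	ThVp-1a	Vp-1Ba	0.90	0.40	light red	white	absent	easy
1654	ThVp-1c	Vp-1Bc	0.62	0.01	blue	white	absent	hard
1674	ThVp-1b	Vp-1Bc	0.78	0.44	light red	white	present	easy
1689	ThVp-1a	Vp-1Bc	0.73	0.44	light red	white	absent	easy
1690	ThVp-1a	Vp-1Ba	0.78	0.66	light red	white	absent	easy
1692	ThVp-1b	Vp-1Bc	0.60	0.62	dark red	white	absent	easy
1735	ThVp-1d	Vp-1Ba	0.42	0.08	light red	white	absent	easy
1737	ThVp-1a	hg	0.61	0.48	dark red	white	absent	easy
1744	ThVp-1a	Vp-1Ba	0.73	0.12	light red	white	absent	easy
1745	ThVp-1d	Vp-1Ba	0.61	0.09	light red	white	absent	easy
1748	ThVp-1a	Vp-1Ba	0.72	0.07	light red	white	absent	easy
1755	ThVp-1a	Vp-1Ba	0.90	0.45	light red	red	absent	easy
1761	ThVp-1a	Vp-1Bc	0.91		dark red	white	absent	easy
1770	ThVp-1b	Vp-1Ba	0.99	0.58	light red	white	absent	easy
1772	ThVp-1c	Vp-1Ba	0.94	0.81	light red	white	small	easy
1774	ThVp-1c	Vp-1Ba	0.45	0.12	dark red	white	small	easy
1777	ThVp-1a	Vp-1Ba	0.60	0.29	light red	white	absent	easy
1780	ThVp-1d	Vp-1Ba	0.61	0.01	light red	white	absent	easy
1783	ThVp-1a	hg	0.71	0.33	light red	white	absent	easy
1784	ThVp-1c	Vp-1Bc	0.95	0.81	light red	white	absent	easy
1788	ThVp-1a	hg	0.93		light red	white	absent	easy
1792	ThVp-1c	hg	0.93	0.89	light red	red	absent	easy
1803	ThVp-1c	Vp-1Bc	0.97	0.86	light red	white	small	easy
1805	ThVp-1c	Vp-1Ba	0.92	0.65	light red	white	absent	easy
1842	ThVp-1a	Vp-1Bc	0.87		light red	white	absent	easy
1866	ThVp-1a	Vp-1Ba	0.74	0.52	light red	red	absent	easy
1868	ThVp-1c	hg	0.85	0.46	light red	white	absent	easy
1869	ThVp-1c	Vp-1Ba	0.87	0.29	dark red	white	small	easy
1872	ThVp-1c	Vp-1Ba	0.99	0.69	dark red	red	present	easy
1874	ThVp-1a	Vp-1Bc	0.86	0.09	dark red	red	absent	easy
1876	ThVp-1d	hg	0.52	0.25	light red	white	absent	easy
1877	ThVp-1a	hg	0.81	0.51	light red	white	absent	easy
1878	ThVp-1a	Vp-1Ba	0.68	0.45	light red	white	absent	easy
2087	ThVp-1b	Vp-1Bc	0.73	0.41	dark red	white	absent	easy
3215	ThVp-1c	hg	0.85	0.44	light red	white	absent	easy
3240	ThVp-1c	Vp-1Bc	0.80	0.54	light red	white	absent	easy
4015	ThVp-1b	Vp-1Bc	0.68	0.64	dark red	white	absent	easy
4023	ThVp-1b	Vp-1Bc	0.80	0.59	dark red	white	absent	easy
4044	ThVp-1a	Vp-1Ba	0.98	0.86	light red	white	absent	easy
4056	hg	hg	0.74	0.89		white	absent	easy
4061	ThVp-1b	Vp-1Ba	0.83	0.64	light red	white	absent	easy
4082	ThVp-1a	Vp-1Ba	0.74	0.89	light red	white	small	easy
5156	ThVp-1d	Vp-1Bc	0.64	0.47	light red	white	absent	easy
5542	ThVp-1a	hg	0.82		light red		absent	easy
5795	ThVp-1d	Vp-1Ba	0.77	0.43	light red	white	absent	easy
1416-bo	ThVp-1a	Vp-1Bc	0.42	0.15	dark red	white	absent	easy
1416-o	ThVp-1a	Vp-1Bc	0.84	0.92	light red	white	present	easy
150-b	ThVp-1a	Vp-1Ba	0.75	0.63	light red	white	small	easy
150-k	ThVp-1c	Vp-1Bc	0.41	0.2	light red	red	small	easy
1665-o	ThVp-1c	hg	0.75	0.65	light red	white	present	easy
1665-h	ThVp-1c	hz	0.67		light red	white	small	easy
1765-b	ThVp-1d	Vp-1Ba	0.71		light red	white	absent	easy
1765-k	ThVp-1d	Vp-1Ba	0.15	0.02	light red	red	absent	easy
1795-so	ThVp-1a	Vp-1Ba	0.69		dark red	white	present	easy
1795-slo	hg	Vp-1Ba	0.66	0.47	dark red	white	small	easy
1804-b	ThVp-1a	hz	0.87		light red	white	absent	easy
1804-k	ThVp-1a	Vp-1Bc	0.82	0.43	light red	red	absent	easy
1807-o	ThVp-1c	Vp-1Ba	0.81	0.57	light red	white	present	easy
1807-h	ThVp-1c	Vp-1Ba	0.85		light red	white	small	easy
1861-bo	ThVp-1a	hz	0.82		light red	white	absent	easy
1865-bkbk	ThVp-1c	Vp-1Bc	0.94		dark red	white	absent	easy
1865-bkk	ThVp-1c	Vp-1Bc	0.97		dark red	red	absent	easy
1870-bo	ThVp-1a	Vp-1Ba	0.80		light red	white	absent	easy
ZP26	ThVp-1a	Vp-1Ba	0.86	0.60	light red	white	absent	easy
M169	ThVp-1b	Vp-1Bc	0.70	0.44	light red	white	absent	easy
M3202	ThVp-1a	Vp-1Ba	0.84	0.65	light red	white	absent	easy
Otrastayushchaya 38	ThVp-1a	Vp-1Bc	0.79	0.45	light red	white	small	easy
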