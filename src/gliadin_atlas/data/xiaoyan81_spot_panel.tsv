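spot_id	XY81	DLGliA1	DLGliB1	DLGliD1	DLGliA2	DLGliB2	DLGliD2	mixture
spot-01	1	0	1	1	1	1	1	0
spot-02	1	0	1	1	1	1	1	0
spot-03	1	0	1	1	1	1	1	0
spot-04	1	0	1	1	1	1	1	0
spot-05	1	0	1	1	1	1	1	0
spot-06	1	0	1	1	1	1	1	0
spot-07	1	0	1	1	1	1	1	0
spot-08	1	0	1	1	1	1	1	0
spot-09	1	0	1	1	1	1	1	0
spot-10	1	0	1	1	1	1	1	0
spot-11	1	1	0	1	1	1	1	0
spot-12	1	1	0	1	1	1	1	0
spot-13	1	1	0	1	1	1	1	0
spot-14	1	1	0	1	1	1	1	0
spot-15	1	1	0	1	1	1	1	0
spot-16	1	1	0	1	1	1	1	0
spot-17	1	1	0	1	1	1	1	0
spot-18	1	1	0	1	1	1	1	0
spot-19	1	1	0	1	1	1	1	0
spot-20	1	1	0	1	1	1	1	0
spot-21	1	1	0	1	1	1	1	0
spot-22	1	1	0	1	1	1	1	0
spot-23	1	1	0	1	1	1	1	0
spot-24	1	1	0	1	1	1	1	0
spot-25	1	1	0	1	1	1	1	0
spot-26	1	1	0	1	1	1	1	0
spot-27	1	1	0	1	1	1	1	0
spot-29	1	1	1	0	1	1	1	0
spot-30	1	1	1	0	1	1	1	0
spot-31	1	1	1	0	1	1	1	0
spot-32	1	1	1	0	1	1	1	0
spot-33	1	1	1	0	1	1	1	0
spot-34	1	1	1	0	1	1	1	0
spot-35	1	1	1	0	1	1	1	0
spot-36	1	1	1	0	1	1	1	0
spot-37	1	1	1	0	1	1	1	0
spot-38	1	1	1	0	1	1	1	0
spot-39	1	1	1	0	1	1	1	0
spot-40	1	1	1	0	1	1	1	0
spot-41	1	1	1	0	1	1	1	0
spot-42	1	1	1	0	1	1	1	0
spot-43	1	1	1	0	1	1	1	0
spot-44	1	1	1	0	1	1	1	0
spot-45	1	1	1	0	1	1	1	0
spot-46	1	1	1	0	1	1	1	0
spot-47	1	1	1	0	1	1	1	0
spot-48	1	1	1	0	1	1	1	0
spot-49	1	1	1	1	0	1	1	0
spot-50	1	1	1	1	0	1	1	0
spot-51	1	1	1	1	0	1	1	0
spot-52	1	1	1	1	0	1	1	0
spot-53	1	1	1	1	0	1	1	0
spot-54	1	1	1	1	0	1	1	0
spot-55	1	1	1	1	0	1	1	0
spot-56	1	1	1	1	0	1	1	0
spot-57	1	1	1	1	0	1	1	0
spot-58	1	1	1	1	0	1	1	0
spot-59	1	1	1	1	0	1	1	0
spot-60	1	1	1	1	0	1	1	0
spot-61	1	1	1	1	0	1	1	0
spot-62	1	1	1	1	0	1	1	0
spot-63	1	1	1	1	0	1	1	0
spot-64	1	1	1	1	1	0	1	0
spot-65	1	1	1	1	1	0	1	0
spot-66	1	1	1	1	1	0	1	0
spot-67	1	1	1	1	1	0	1	0
spot-68	1	1	1	1	1	0	1	0
spot-69	1	1	1	1	1	0	1	0
spot-70	1	1	1	1	1	0	1	0
spot-71	1	1	1	1	1	0	1	0
spot-72	1	1	1	1	1	0	1	0
spot-73	1	1	1	1	1	0	1	0
spot-74	1	1	1	1	1	0	1	0
spot-75	1	1	1	1	1	0	1	0
spot-76	1	1	1	1	1	0	1	0
spot-77	1	1	1	1	1	1	0	0
spot-78	1	1	1	1	1	1	0	0
spot-79	1	1	1	1	1	1	0	0
spot-80	1	1	1	1	1	1	0	0
spot-81	1	1	1	1	1	1	0	0
spot-82	1	1	1	1	1	1	0	0
spot-83	1	1	1	1	1	1	0	0
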