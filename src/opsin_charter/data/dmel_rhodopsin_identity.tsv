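#identity	Rh1	Rh2	Rh3	Rh4	Rh5	Rh6	Rh7	BtOpsin	BtMelanopsin
Rh1	100.00	69.16	35.38	35.12	32.17	51.76	29.75	24.71	31.09
Rh2	69.16	100.00	34.38	35.71	32.28	51.21	28.87	24.42	30.44
Rh3	35.38	34.38	100.00	73.01	40.83	31.16	30.28	22.70	28.45
Rh4	35.12	35.71	73.01	100.00	44.44	32.79	30.42	23.56	29.89
Rh5	32.17	32.28	40.83	44.44	100.00	30.35	30.36	22.41	27.22
Rh6	51.76	51.21	31.16	32.79	30.35	100.00	27.10	25.00	31.70
Rh7	29.75	28.87	30.28	30.42	30.36	27.10	100.00	23.27	24.47
BtOpsin	24.71	24.42	22.70	23.56	22.41	25.00	23.27	100.00	25.57
BtMelanopsin	31.09	30.44	28.45	29.89	27.22	31.70	24.47	25.57	100.00
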