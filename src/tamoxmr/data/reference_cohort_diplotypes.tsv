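allele_a	allele_b	duplicated	count
*1	*2	False	44
*1	*1	False	33
*2	*2	False	10
*1	*41	False	24
*2	*41	False	10
*1	*10	False	7
*2	*10	False	2
*1	*4	False	51
*2	*4	False	30
*1	*5	False	6
*1	*3	False	4
*2	*5	False	3
*1	*6	False	1
*2	*3	False	1
*2	*6	False	1
*41	*41	False	1
*10	*10	False	1
*10	*41	False	1
*4	*41	False	6
*4	*10	False	3
*4	*17	False	1
*5	*41	False	1
*4	*4	False	15
*3	*4	False	2
*4	*5	False	2
*4	*6	False	1
*1	*2	True	10
*1	*1	True	5
*2	*2	True	3
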