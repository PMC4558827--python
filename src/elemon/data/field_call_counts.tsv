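session	call_type	count
Bela Bela 2011	rumble	633
Bela Bela 2011	bark	1
Bela Bela 2011	noisy roar	18
Bela Bela 2011	tonal roar	0
Bela Bela 2011	mixed roar	0
Bela Bela 2011	trumpet	15
Bela Bela 2011	snort	3
Bela Bela 2011	grunt	0
Bela Bela 2011	unknown	11
Addo 2011	rumble	925
Addo 2011	bark	15
Addo 2011	noisy roar	41
Addo 2011	tonal roar	34
Addo 2011	mixed roar	56
Addo 2011	trumpet	166
Addo 2011	snort	103
Addo 2011	grunt	8
Addo 2011	unknown	22
Addo 2012	rumble	529
Addo 2012	bark	1
Addo 2012	noisy roar	19
Addo 2012	tonal roar	23
Addo 2012	mixed roar	20
Addo 2012	trumpet	137
Addo 2012	snort	87
Addo 2012	grunt	7
Addo 2012	unknown	6
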