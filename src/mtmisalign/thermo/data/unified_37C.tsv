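# Nearest-neighbor DNA duplex free energies, kcal/mol, 37 C, 1 M NaCl.
# dG37 = dH - 310.15*dS/1000, from the published dH/dS tables:
#   Watson-Crick stacks ........ Allawi & SantaLucia (1997) unified set
#   internal single mismatches . Allawi & SantaLucia (1997, 1998a-c),
#                                Peyret et al. (1999)
#   initiation, terminal A:T ... SantaLucia & Hicks (2004)
# Context notation XY/WZ: top strand 5'-XY-3' paired with bottom 3'-WZ-5';
# X:W and Y:Z are the two base pairs of the stack.
# Loop row: dG(s) = loop_a + loop_c * ln(s) for an internal loop/bulge of
# s unpaired nucleotides in total (Jacobson-Stockmayer form); loops larger
# than max_loop are inadmissible.
section	context	value
meta	temperature_K	310.15
meta	R_kcal_mol_K	0.0019872
stack	AA/TT	-1.0147
stack	AT/TA	-0.8729
stack	CA/GT	-1.4596
stack	CG/GC	-2.1639
stack	CT/GA	-1.2869
stack	GA/CT	-1.3147
stack	GC/CG	-2.2323
stack	GG/CC	-1.8280
stack	GT/CA	-1.4526
stack	TA/AT	-0.5938
mismatch	AA/TA	0.6727
mismatch	AA/TC	0.8733
mismatch	AA/TG	0.1133
mismatch	AC/TA	0.7718
mismatch	AC/TC	1.3647
mismatch	AC/TT	0.6380
mismatch	AG/TA	0.0133
mismatch	AG/TG	-0.1536
mismatch	AG/TT	0.7209
mismatch	AT/TC	0.7229
mismatch	AT/TG	0.0742
mismatch	AT/TT	0.6496
mismatch	CA/GA	0.4026
mismatch	CA/GC	0.7524
mismatch	CA/GG	0.0133
mismatch	CC/GA	0.7861
mismatch	CC/GC	0.7331
mismatch	CC/GT	0.5957
mismatch	CG/GA	0.0940
mismatch	CG/GG	-0.1547
mismatch	CG/GT	-0.4712
mismatch	CT/GC	0.3919
mismatch	CT/GG	-0.3188
mismatch	CT/GT	-0.0996
mismatch	GA/CA	0.1395
mismatch	GA/CC	0.7959
mismatch	GA/CG	-0.2898
mismatch	GC/CA	0.4786
mismatch	GC/CC	0.8397
mismatch	GC/CT	0.6252
mismatch	GG/CA	-0.4925
mismatch	GG/CG	-1.0996
mismatch	GG/CT	0.0744
mismatch	GT/CC	1.0130
mismatch	GT/CG	-0.5852
mismatch	GT/CT	0.4053
mismatch	TA/AA	0.6991
mismatch	TA/AC	0.9188
mismatch	TA/AG	0.4829
mismatch	TC/AA	1.3350
mismatch	TC/AC	1.0135
mismatch	TC/AT	0.9829
mismatch	TG/AA	0.7049
mismatch	TG/AG	0.4835
mismatch	TG/AT	0.4273
mismatch	TT/AC	0.7829
mismatch	TT/AG	0.3438
mismatch	TT/AT	0.6652
init	duplex	1.9368
init	terminal_AT	0.0600
loop	loop_a	3.2000
loop	loop_c	1.5000
loop	max_loop	6
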