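# RNA-RNA nearest-neighbor helix parameters, Turner 2004 set
# (Xia et al. 1998 Watson-Crick stacks; Mathews et al. 1999/2004
#  G.U wobble stacks; duplex initiation and terminal A.U/G.U
#  penalty from the same set). Stack written 5'WX3'/3'ZY5'.
# dH kcal/mol; dS cal/(mol.K); dG37 kcal/mol as published.
name	dH	dS	dG37
AA/UU	-6.80	-19.0231	-0.90
AC/UG	-11.40	-29.6631	-2.20
AG/UC	-10.50	-27.0837	-2.10
AG/UU	-3.20	-8.3830	-0.60
AU/UA	-9.40	-26.7612	-1.10
AU/UG	-8.80	-23.8594	-1.40
CA/GU	-10.40	-26.7612	-2.10
CC/GG	-13.40	-32.5649	-3.30
CG/GC	-10.60	-26.4388	-2.40
CG/GU	-5.60	-13.5418	-1.40
CU/GG	-12.10	-32.2425	-2.10
GA/CU	-12.40	-32.2425	-2.40
GA/UU	-12.80	-37.0788	-1.30
GC/CG	-14.90	-37.0788	-3.40
GC/UG	-12.60	-32.5649	-2.50
GG/CU	-8.30	-21.9249	-1.50
GG/UU	-13.50	-41.9152	-0.50
GU/UG	-14.60	-51.2655	1.30
UA/AU	-7.70	-20.6352	-1.30
UA/GU	-7.00	-19.3455	-1.00
UG/GU	-9.30	-30.9528	0.30
init	3.60	-1.6121	4.10
terminal_au	3.70	10.3176	0.50
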