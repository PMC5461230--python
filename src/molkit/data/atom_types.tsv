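# Declarative atom-type table.
# Columns (tab-separated):
#   name  symbol  charge  hybridization  lone_pairs  bond_orders
# bond_orders is a comma-separated multiset over {s,d,t} counting implicit
# hydrogens as single bonds; "-" means no bonds (bare ion).
# Lone-pair counts for charged species follow octet bookkeeping.
H.sp3	H	0	s	0	s
B.planar3	B	0	planar3	0	s,s,s
B.minus.sp3	B	-1	sp3	0	s,s,s,s
C.sp3	C	0	sp3	0	s,s,s,s
C.sp2	C	0	sp2	0	s,s,d
C.sp1	C	0	sp1	0	s,t
C.allene	C	0	sp1	0	d,d
C.plus.planar	C	1	planar3	0	s,s,s
C.minus.sp3	C	-1	sp3	1	s,s,s
C.minus.sp2	C	-1	sp2	1	s,d
C.minus.sp1	C	-1	sp1	1	t
N.sp3	N	0	sp3	1	s,s,s
N.sp2	N	0	sp2	1	s,d
N.sp1	N	0	sp1	1	t
N.plus.sp3	N	1	sp3	0	s,s,s,s
N.plus.sp2	N	1	sp2	0	s,s,d
N.plus.sp1	N	1	sp1	0	s,t
N.plus.allene	N	1	sp1	0	d,d
N.minus.sp3	N	-1	sp3	2	s,s
N.minus.sp2	N	-1	sp2	2	d
O.sp3	O	0	sp3	2	s,s
O.sp2	O	0	sp2	2	d
O.plus.sp3	O	1	sp3	1	s,s,s
O.plus.sp2	O	1	sp2	1	s,d
O.minus.sp3	O	-1	sp3	3	s
P.sp3	P	0	sp3	1	s,s,s
P.ate	P	0	unset	0	s,s,s,d
P.plus.sp3	P	1	sp3	0	s,s,s,s
P.minus.sp3	P	-1	sp3	2	s,s
S.sp3	S	0	sp3	2	s,s
S.sp2	S	0	sp2	2	d
S.inyl	S	0	unset	1	s,s,d
S.onyl	S	0	unset	0	s,s,d,d
S.plus.sp3	S	1	sp3	1	s,s,s
S.minus.sp3	S	-1	sp3	3	s
F.sp3	F	0	sp3	3	s
F.minus	F	-1	sp3	4	-
Cl.sp3	Cl	0	sp3	3	s
Cl.minus	Cl	-1	sp3	4	-
Br.sp3	Br	0	sp3	3	s
Br.minus	Br	-1	sp3	4	-
I.sp3	I	0	sp3	3	s
I.minus	I	-1	sp3	4	-
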