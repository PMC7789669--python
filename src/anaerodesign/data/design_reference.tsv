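gene	category	n_domains	pfam	sources
ArgI	nitrogen metabolism	1	PF00491	PDC
GlsA	nitrogen metabolism	1	PF04960	PDC,T
FocA	nitrogen metabolism	1	PF01226	PDC,T
PucR	nitrogen metabolism	1	PF13556	PDC,T
NifS	nitrogen metabolism	1	PF01458	PDC,T
NifU	nitrogen metabolism	1	PF01458	PDC,T
RnfH	nitrogen metabolism	1	PF03658	PDC,T
RnfA	nitrogen metabolism	1	PF02508	PDC,T
Nqr2	nitrogen metabolism	1	PF03116	PDC,T
RnfD	nitrogen metabolism	1	PF03116	PDC,T
RnfE	nitrogen metabolism	1	PF02508	PDC,T
Nmo	nitrogen metabolism	1	PF03060	PDC,T
AnsB	nitrogen metabolism	1	PF06089	PDC,T
DauB	nitrogen metabolism	1	PF02423	PDC,T
DauA	nitrogen metabolism	1	PF01266	PDC,T
DauR	nitrogen metabolism	1	PF08348	PDC,T
NarK1	nitrogen metabolism	1	PF07690	PDC,T
NarK2	nitrogen metabolism	1	PF07690	PDC,T
NarG	nitrogen metabolism	3	PF14710;PF00384;PF01568	PDC,T
NarH	nitrogen metabolism	2	PF13247;PF14711	PDC,T
NarJ	nitrogen metabolism	1	PF02613	PDC,T
NarI	nitrogen metabolism	1	PF02665	PDC,T
NarX	nitrogen metabolism	4	PF02518;PF00672;PF07730;PF13675	PDC,T
NarL	nitrogen metabolism	2	PF00072;PF00196	PDC,T
NirJ	nitrogen metabolism	1	PF04055	PDC,T
NirF	nitrogen metabolism	1	PF02239	PDC,T
NirL	nitrogen metabolism	1	PF02239	PDC,T
NirQ	nitrogen metabolism	1	PF07728	PDC,T
NirM	nitrogen metabolism	1	PF13442	PDC,T
NirS	nitrogen metabolism	2	PF13442;PF02239	PDC,T
MoaA1	nitrogen metabolism	3	PF00994;PF03453;PF03454	PDC
MoaB1	nitrogen metabolism	1	PF00994	PDC
NorB	nitrogen metabolism	1	PF00115	PDC,T
NorC	nitrogen metabolism	1	PF00034	PDC,T
NosR	nitrogen metabolism	1	PF04205	PDC,T
HyaB	hydrogenases	1	PF00374	PDC
HybO	hydrogenases	1	PF14720	PDC
HupF	hydrogenases	1	PF01455	PDC
HycI	hydrogenases	1	PF01750	PDC
HypA	hydrogenases	1	PF01924	PDC
HupH	hydrogenases	1	PF04809	PDC
HyaE	hydrogenases	1	PF07449	PDC
HybE	hydrogenases	1	PF11939	PDC
HupE	hydrogenases	1	PF04955	PDC
NirC	cytochrome C	1	PF02335	PDC
PyrK-PyrD	pyrimidine & amino acid biosynthesis	2	PF01180;PF00977	GSM
NrdD-NrdG	pyrimidine & amino acid biosynthesis	2	PF13597;PF04055	GSM
DNR	pyrimidine & amino acid biosynthesis	2	PF00027;PF13545	PDC
AckA	ATP generation	1	PF00871	PDC,GSM
DUF1924	unknown function	1	PF09086	PDC
DUF1588	unknown function	1	PF07627	PDC
DUF1587	unknown function	1	PF07626	PDC
DUF1592	unknown function	1	PF07631	PDC
DUF1595	unknown function	1	PF07637	PDC
DUF2459	unknown function	1	PF09601	PDC
DUF3865	unknown function	1	PF12981	PDC
RyR	unknown function	1	PF02026	PDC
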