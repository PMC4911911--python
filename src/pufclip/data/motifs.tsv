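# Bundled motif table: name, IUPAC pattern, optional upstream context "BASE@offsets".
# The canonical FBE, its high-affinity context variants and the 7-mer are the
# published elements; half-mers are the UGU-core fragments shared by PUF sites.
# The four "invitro*_synthetic" rows are editable synthetic stand-ins for
# in vitro selection motifs whose exact strings are not bundled here; replace
# them with your own patterns as needed.
name	pattern	context
FBE	UGUNNNAU
FBE_-1C	UGUNNNAU	C@-1
FBE_-2C	UGUNNNAU	C@-2
7mer	UGURNAU
7mer_refined	UGUGAAUR
halfmer_UGU	UGU
halfmer_CUGU	CUGU
alt_ug_halfmer	UGUGAUGUG
egl4_element	UGUGUAUAUA
invitro4_synthetic	UGUAUAUA
invitro5_synthetic	UGUACAUA
invitro6_synthetic	UGUAAAUA
invitro7_synthetic	UGUGCAUA
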