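label	edited_sites	pattern	protein
ABD edited form	ABD	GnG-nnn-AAn-nnn-Gnn	VNV
AD edited form	AD	GnA-nnn-AAn-nnn-Gnn	VNV
AB edited form	AB	GnG-nnn-AAn-nnn-Ann	VNI
A edited form	A	GnA-nnn-AAn-nnn-Ann	VNI
ABCD edited form	ABCD	GnG-nnn-AGn-nnn-Gnn	VSV
ACD edited form	ACD	GnA-nnn-AGn-nnn-Gnn	VSV
UNEDITED	-	AnA-nnn-AAn-nnn-Ann	INI
ABECD edited form	ABECD	GnG-nnn-GGn-nnn-Gnn	VGV
AECD edited form	AECD	GnA-nnn-GGn-nnn-Gnn	VGV
ABC edited form	ABC	GnG-nnn-AGn-nnn-Ann	VSI
AC edited form	AC	GnA-nnn-AGn-nnn-Ann	VSI
B edited form	B	AnG-nnn-AAn-nnn-Ann	MNI
E edited form	E	AnA-nnn-GAn-nnn-Ann	IDI
C edited form	C	AnA-nnn-AGn-nnn-Ann	ISI
D edited form	D	AnA-nnn-AAn-nnn-Gnn	INV
ABED edited form	ABED	GnG-nnn-GAn-nnn-Gnn	VDV
AED edited form	AED	GnA-nnn-GAn-nnn-Gnn	VDV
ABE edited form	ABE	GnG-nnn-GAn-nnn-Ann	VDI
AE edited form	AE	GnA-nnn-GAn-nnn-Ann	VDI
CD edited form	CD	AnA-nnn-AGn-nnn-Gnn	ISV
BD edited form	BD	AnG-nnn-AAn-nnn-Gnn	MNV
ABEC edited form	ABEC	GnG-nnn-GGn-nnn-Ann	VGI
AEC edited form	AEC	GnA-nnn-GGn-nnn-Ann	VGI
ECD edited form	ECD	AnA-nnn-GGn-nnn-Gnn	IGV
BC edited form	BC	AnG-nnn-AGn-nnn-Ann	MSI
EC edited form	EC	AnA-nnn-GGn-nnn-Ann	IGI
ED edited form	ED	AnA-nnn-GAn-nnn-Gnn	IDV
BE edited form	BE	AnG-nnn-GAn-nnn-Ann	MDI
BEC edited form	BEC	AnG-nnn-GGn-nnn-Ann	MGI
BED edited form	BED	AnG-nnn-GAn-nnn-Gnn	MDV
BCD edited form	BCD	AnG-nnn-AGn-nnn-Gnn	MSV
BECD edited form	BECD	AnG-nnn-GGn-nnn-Gnn	MGV
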