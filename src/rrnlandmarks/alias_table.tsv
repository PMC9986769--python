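# Landmark label aliases (TSV: alias <TAB> canonical symbol).
# Lookup normalizes case and strips spaces/hyphens/underscores, so
# "Condylar-Left" and "condylar left" both resolve via "condylarleft".
menton	Me
gnathion	Gn
pogonion	Pg
b point	B
bpoint	B
point b	B
infradentale	Id
coronoid left	CorL
left coronoid	CorL
coronoidale left	CorL
coronoid right	CorR
right coronoid	CorR
coronoidale right	CorR
condylar left	CdL
condyle left	CdL
left condyle	CdL
condylion left	CdL
condylar right	CdR
condyle right	CdR
right condyle	CdR
condylion right	CdR
anterior nasal spine	ANS
ans point	ANS
a point	A
point a	A
subspinale	A
prosthion	Pr
prostion	Pr
posterior nasal spine	PNS
nasion	Na
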