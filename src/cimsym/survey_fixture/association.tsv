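strain_id	host_id	genus	host_species
Wolbachia-C1	C1	Wolbachia	Afrocimex constrictus
Wolbachia-C5	C5	Wolbachia	Primicimex cavernis
Wolbachia-C12-high	C12	Wolbachia	Cyanolicimex patagonicus
Wolbachia-C12-low	C12	Wolbachia	Cyanolicimex patagonicus
Wolbachia-C21-high	C21	Wolbachia	Psitticimex uritui
Wolbachia-C21-low	C21	Wolbachia	Psitticimex uritui
Wolbachia-C44	C44	Wolbachia	Paracimex sp
Wolbachia-C49	C49	Wolbachia	Cimex vicarius
Wolbachia-C51-high	C51	Wolbachia	Cimex hirundinis
Wolbachia-C51-low	C51	Wolbachia	Cimex hirundinis
Wolbachia-C56	C56	Wolbachia	Cimex lectularius (bat)
Wolbachia-C57	C57	Wolbachia	Cimex lectularius (human)
Wolbachia-C61	C61	Wolbachia	Cimex hemipterus
Wolbachia-C66	C66	Wolbachia	Cimex adjunctus
Symbiopectobacterium-C19	C19	Symbiopectobacterium	Cacodmus villosus
Symbiopectobacterium-C28	C28	Symbiopectobacterium	Cacodmus vicinus
Symbiopectobacterium-C41	C41	Symbiopectobacterium	Leptocimex duplicatus
Symbiopectobacterium-C57	C57	Symbiopectobacterium	Cimex lectularius (human)
Symbiopectobacterium-C61	C61	Symbiopectobacterium	Cimex hemipterus
Sodalis-C5	C5	Sodalis	Primicimex cavernis
Sodalis-C12	C12	Sodalis	Cyanolicimex patagonicus
Sodalis-C21	C21	Sodalis	Psitticimex uritui
Serratia-C44	C44	Serratia	Paracimex sp
Tisiphia-C1	C1	Tisiphia	Afrocimex constrictus
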