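# canonical	category	synonyms (| separated; may be empty)
Tris	buffer	Tris-HCl|tris buffer|tris(hydroxymethyl)aminomethane
HEPES	buffer	4-(2-hydroxyethyl)-1-piperazineethanesulfonic acid
phosphate	buffer	sodium phosphate|potassium phosphate|phosphate buffer|phosphate-buffered saline|PBS
MOPS	buffer	3-(N-morpholino)propanesulfonic acid
CAPS	buffer	N-cyclohexyl-3-aminopropanesulfonic acid
MES	buffer	2-(N-morpholino)ethanesulfonic acid
glycine-HCl	buffer	glycine hydrochloride
acetate	buffer	sodium acetate|ammonium acetate
carbonate-bicarbonate	buffer	sodium carbonate|sodium bicarbonate|carbonate buffer
citrate	buffer	citrate buffer
Bis-Tris	buffer
NaCl	salt	sodium chloride
KCl	salt	potassium chloride
MgCl2	salt	magnesium chloride
CaCl2	salt	calcium chloride
ammonium sulfate	salt	(NH4)2SO4
DTT	reducing_agent	dithiothreitol|DL-dithiothreitol
TCEP	reducing_agent	tris(2-carboxyethyl)phosphine
beta-mercaptoethanol	reducing_agent	β-mercaptoethanol|2-mercaptoethanol|BME
glutathione	reducing_agent	reduced glutathione|GSH
EDTA	chelator	ethylenediaminetetraacetic acid
EGTA	chelator	egtazic acid
DDM	detergent	n-dodecyl-β-D-maltoside|dodecyl maltoside
CHS	detergent	cholesteryl hemisuccinate
GDN	detergent	glyco-diosgenin
LMNG	detergent	lauryl maltose neopentyl glycol
digitonin	detergent
Tween 20	detergent	polysorbate 20
Triton X-100	detergent	TritonX-100
NP-40	detergent	Nonidet P-40|IGEPAL CA-630
SDS	detergent	sodium dodecyl sulfate
OG	detergent	octyl glucoside|n-octyl-β-D-glucoside
PMSF	inhibitor	phenylmethylsulfonyl fluoride
NaF	inhibitor	sodium fluoride
Na3VO4	inhibitor	sodium orthovanadate
benzamidine	inhibitor
leupeptin	inhibitor
aprotinin	inhibitor
glycerol	additive
PEG	additive	polyethylene glycol|PEG 3350|PEG 400
sucrose	additive
urea	additive
arginine	additive	L-arginine
imidazole	additive
ATP	additive	adenosine triphosphate
DMSO	additive	dimethyl sulfoxide
glutaraldehyde	crosslinker
BS3	crosslinker	bis(sulfosuccinimidyl)suberate
DSS	crosslinker	disuccinimidyl suberate
formaldehyde	crosslinker	paraformaldehyde
IPTG	other	isopropyl β-D-1-thiogalactopyranoside|isopropyl beta-D-1-thiogalactopyranoside
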