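# Biolog PM1 well -> metabolite base id mapping (editable).
# Ids follow BiGG conventions where a standard id exists; wells whose compound
# has no exchange reaction in a given model are excluded from scoring and
# logged. A1 is the negative-control well (no carbon source).
well	metabolite_id	name
A2	arab__L	L-arabinose
A3	acgam	N-acetyl-D-glucosamine
A4	sbt__D	D-sorbitol
A5	succ	succinate
A6	gal	D-galactose
A7	lcts	lactose
A8	fuc__L	L-fucose
A9	glc__D	D-glucose
A10	acmana	N-acetyl-D-mannosamine
A11	malt	maltose
A12	fru	D-fructose
B1	tre	trehalose
B2	man	D-mannose
B3	ac	acetate
B4	cit	citrate
B5	for	formate
B6	glcn	D-gluconate
B7	glcur	D-glucuronate
B8	xyl__D	D-xylose
B9	mnl	D-mannitol
B10	lac__L	L-lactate
B11	rmn	L-rhamnose
B12	melib	melibiose
C1	glyc	glycerol
C2	fum	fumarate
C3	akg	2-oxoglutarate
C4	gam	D-glucosamine
C5	rib__D	D-ribose
C6	mal__L	L-malate
C7	sucr	sucrose
C8	pyr	pyruvate
C9	galctn__D	D-galactonate
C10	lyx__L	L-lyxose
C11	glyclt	glycolate
C12	inost	myo-inositol
D1	ala__D	D-alanine
D2	ala__L	L-alanine
D3	asn__L	L-asparagine
D4	asp__L	L-aspartate
D5	glu__L	L-glutamate
D6	gln__L	L-glutamine
D7	gly	glycine
D8	his__L	L-histidine
D9	pro__L	L-proline
D10	ser__L	L-serine
D11	thr__L	L-threonine
D12	arg__L	L-arginine
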