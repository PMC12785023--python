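# Curated annotation table: name <TAB> elemental formula <TAB> compound class
# Monoisotopic masses are computed from the formula at load time.
# MS1 matches against this table are tentative shortlists, not identifications.
dCTP	C9H16N3O13P3	nucleotide
dTTP	C10H17N2O14P3	nucleotide
dATP	C10H16N5O12P3	nucleotide
dGTP	C10H16N5O13P3	nucleotide
ATP	C10H16N5O13P3	nucleotide
ADP	C10H15N5O10P2	nucleotide
AMP	C10H14N5O7P	nucleotide
GTP	C10H16N5O14P3	nucleotide
CTP	C9H16N3O14P3	nucleotide
UTP	C9H15N2O15P3	nucleotide
UDP-glucose	C15H24N2O17P2	nucleotide sugar
NAD	C21H27N7O14P2	cofactor
glutathione	C10H17N3O6S	peptide
glucose	C6H12O6	sugar
sucrose	C12H22O11	sugar
trehalose	C12H22O11	sugar
palmitic acid	C16H32O2	fatty acid
stearic acid	C18H36O2	fatty acid
oleic acid	C18H34O2	fatty acid
arachidonic acid	C20H32O2	fatty acid
docosahexaenoic acid	C22H32O2	fatty acid
cholesterol	C27H46O	sterol
LysoPC(16:0)	C24H50NO7P	glycerophospholipid
PC(34:1)	C42H82NO8P	glycerophospholipid
PE(38:4)	C43H78NO8P	glycerophospholipid
PS(36:1)	C42H82NO10P	glycerophospholipid
PI(38:4)	C47H83O13P	glycerophospholipid
PG(34:1)	C40H77O10P	glycerophospholipid
PA(36:2)	C39H73O8P	glycerophospholipid
SM(d34:1)	C39H79N2O6P	sphingolipid
ceramide(d34:1)	C34H67NO3	sphingolipid
TG(52:2)	C55H102O6	triacylglycerol
TG(54:4)	C57H102O6	triacylglycerol
spermine	C10H26N4	polyamine
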