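# Synthetic placeholder list of plasmid-marker domain accessions.
# These are NOT the curated plasmid-specific PFAM accessions used for real
# classification runs (supply that list at runtime); they exist so fixtures,
# examples and the synthetic replicon panel have a marker vocabulary.
PFSYN0001
PFSYN0002
PFSYN0003
PFSYN0004
PFSYN0005
PFSYN0006
PFSYN0007
PFSYN0008
PFSYN0009
PFSYN0010
PFSYN0011
PFSYN0012
PFSYN0013
PFSYN0014
PFSYN0015
PFSYN0016
PFSYN0017
PFSYN0018
PFSYN0019
PFSYN0020
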