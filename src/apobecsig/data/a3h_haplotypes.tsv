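# Synthetic default A3H haplotype-defining allele table (site, haplotype, allele).
# Encodes the published protein-level dichotomies as tagging SNPs so that every
# haplotype I-VII maps to a unique allele triple:
#   site105: G = Gly105 (haplotype I), A = Arg105 (all others)
#   site15:  C = Asn15 intact, T = tag for the Asn15 deletion (III/IV/VI)
#   site121: A/G/C tags separating the remaining stable/unstable haplotypes
# The nucleotide-level combinations defining haplotypes V and VII are not fixed
# by this package; override with a custom table where real panel data exist.
site_id	haplotype	allele
site15	I	C
site105	I	G
site121	I	A
site15	II	C
site105	II	A
site121	II	A
site15	III	T
site105	III	A
site121	III	A
site15	IV	T
site105	IV	A
site121	IV	G
site15	V	C
site105	V	A
site121	V	G
site15	VI	T
site105	VI	A
site121	VI	C
site15	VII	C
site105	VII	A
site121	VII	C
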