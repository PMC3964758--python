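# Dopamine-increasing "effect" allele per variant, used by the polygenic
# risk score (sum of effect-allele copies across variants).
#
# "absence-of-focal" means the effect allele is *not carrying* the focal
# repeat (the focal repeat lowers dopamine signalling for these two VNTRs).
#
# Note on rs6275: the published hypothesis table pairs the G allele with
# *decreased* dopamine level via increased DRD2 (inhibitory autoreceptor)
# expression, which inverts the usual receptor-expression logic; the mapping
# below encodes that table as printed (effect allele = A).
rs265981: G
rs6275: A
rs1800497: A
rs6280: T
rs1800955: T
DRD4_exon3_VNTR: "7"
DRD5_upstream_VNTR: absence-of-focal
rs1611115: T
rs2519152: T
DAT1_3utr_VNTR: absence-of-focal
rs4680: G
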