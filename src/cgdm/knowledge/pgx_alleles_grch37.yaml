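# Star-allele and promoter-variant definitions used by the pharmacogenomic
# decision-support layer, GRCh37 coordinates (example knowledge table; the
# test suite uses definitions generated on the synthetic FIXTURE1 build).
#
# CYP2C9 decreased-function alleles are defined by one tag SNV each;
# VKORC1 sensitivity is tagged by the -1639 G>A promoter variant rs9923231.
version: "PGx-examples-GRCh37"
genome_build: GRCh37
cyp2c9:
  "*2":
    chromosome: "10"
    position: 96702047
    ref: C
    alt: T
    dbsnp: rs1799853
  "*3":
    chromosome: "10"
    position: 96741053
    ref: A
    alt: C
    dbsnp: rs1057910
vkorc1_1639:
  chromosome: "16"
  position: 31107689
  ref: G
  alt: A
  dbsnp: rs9923231
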