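# Ostrich (Struthio camelus, SCA) homology map against chicken (GGA) units.
# Curated from published comparative FISH/sequence karyotype mapping: every
# tested chicken homolog is conserved whole, except GGA4, whose q-arm
# corresponds to ostrich chromosome 4 while its p-arm remains a separate
# ancestral microchromosome (the q+p fusion happened in the chicken
# lineage).  Intrachromosomal differences are not encoded here.
tgt_chrom	tgt_start	tgt_end	ref_unit	ref_start	ref_end	strand	note
SCA1	NA	NA	1	NA	NA	+	intact homolog
SCA2	NA	NA	2	NA	NA	+	intact homolog
SCA3	NA	NA	3	NA	NA	+	intact homolog
SCA4	NA	NA	4	NA	NA	+	GGA4 q-arm homolog
SCA5	NA	NA	5	NA	NA	+	intact homolog
SCA6	NA	NA	6	NA	NA	+	intact homolog
SCA7	NA	NA	7	NA	NA	+	intact homolog
SCA8	NA	NA	8	NA	NA	+	intact homolog
SCA9	NA	NA	9	NA	NA	+	intact homolog
SCA10	NA	NA	10	NA	NA	+	intact microchromosome
SCA11	NA	NA	11	NA	NA	+	intact microchromosome
SCA12	NA	NA	12	NA	NA	+	intact microchromosome
SCA13	NA	NA	13	NA	NA	+	intact microchromosome
SCA14	NA	NA	14	NA	NA	+	intact microchromosome
SCA15	NA	NA	15	NA	NA	+	intact microchromosome
SCA17	NA	NA	17	NA	NA	+	intact microchromosome
SCA18	NA	NA	18	NA	NA	+	intact microchromosome
SCA19	NA	NA	19	NA	NA	+	intact microchromosome
SCA20	NA	NA	20	NA	NA	+	intact microchromosome
SCA21	NA	NA	21	NA	NA	+	intact microchromosome
SCA22	NA	NA	22	NA	NA	+	intact microchromosome
SCA23	NA	NA	23	NA	NA	+	intact microchromosome
SCA24	NA	NA	24	NA	NA	+	intact microchromosome
SCA26	NA	NA	26	NA	NA	+	intact microchromosome
SCA27	NA	NA	27	NA	NA	+	intact microchromosome
SCA28	NA	NA	28	NA	NA	+	intact microchromosome
SCA4p	NA	NA	4	NA	NA	+	GGA4 p-arm homolog conserved as a separate microchromosome
SCAZ	NA	NA	Z	NA	NA	+	intact sex chromosome
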