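# Budgerigar (Melopsittacus undulatus, MUN) homology map against ancestral
# avian units (chicken numbering; the microchromosome forming chicken 4p is
# its own unit "4p").  Curated from published comparative FISH/sequence
# karyotype mapping of the budgerigar.  The internal partner order within
# the three-homolog fusion chromosomes (MUN4, MUN5, MUN8) is only partially
# determined by the published descriptions; the orders below honor the
# stated pairings and no downstream count depends on the residual ambiguity.
# MUN numbering beyond the published assignments (MUN2, MUN3/6, MUN4/8) is
# by approximate size and is not asserted.
tgt_chrom	tgt_start	tgt_end	ref_unit	ref_start	ref_end	strand	note
MUN1	NA	NA	2	NA	NA	+	intact GGA2 homolog
MUN2	NA	NA	3	NA	NA	+	fused with GGA17 homolog
MUN2	NA	NA	17	NA	NA	+	fused microchromosome
MUN3	NA	NA	1	NA	NA	+	GGA1 half; fission shared with zebra finch lineage
MUN4	NA	NA	5	NA	NA	+	GGA5 half, fused with GGA6 homolog
MUN4	NA	NA	6	NA	NA	+	fused between GGA5 and GGA7 halves
MUN4	NA	NA	7	NA	NA	+	GGA7 half
MUN5	NA	NA	8	NA	NA	+	fused with GGA9 homolog
MUN5	NA	NA	9	NA	NA	+	fused between GGA8 homolog and ancestral 4p microchromosome
MUN5	NA	NA	4p	NA	NA	+	ancestral microchromosome (chicken 4p homolog), fused
MUN6	NA	NA	1	NA	NA	+	GGA1 half
MUN7	NA	NA	4	NA	NA	+	intact GGA4q homolog
MUN8	NA	NA	7	NA	NA	+	GGA7 half, fused with GGA5 half
MUN8	NA	NA	5	NA	NA	+	GGA5 half
MUN8	NA	NA	14	NA	NA	+	fused microchromosome
MUN9	NA	NA	10	NA	NA	+	fused microchromosome pair
MUN9	NA	NA	12	NA	NA	+	fused microchromosome pair
MUN10	NA	NA	13	NA	NA	+	fused microchromosome pair
MUN10	NA	NA	20	NA	NA	+	fused microchromosome pair
MUN11	NA	NA	11	NA	NA	+	intact microchromosome
MUN12	NA	NA	15	NA	NA	+	intact microchromosome
MUN13	NA	NA	18	NA	NA	+	intact microchromosome
MUN14	NA	NA	19	NA	NA	+	intact microchromosome
MUN15	NA	NA	21	NA	NA	+	intact microchromosome
MUN16	NA	NA	22	NA	NA	+	intact microchromosome
MUN17	NA	NA	23	NA	NA	+	intact microchromosome
MUN18	NA	NA	24	NA	NA	+	intact microchromosome
MUN19	NA	NA	26	NA	NA	+	intact microchromosome
MUN20	NA	NA	27	NA	NA	+	intact microchromosome
MUN21	NA	NA	28	NA	NA	+	intact microchromosome
MUNZ	NA	NA	Z	NA	NA	+	intact sex chromosome
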