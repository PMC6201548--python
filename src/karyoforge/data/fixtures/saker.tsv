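# Saker falcon (Falco cherrug, FCH) homology map against chicken (GGA) units.
# Curated from published comparative FISH/sequence karyotype mapping of the
# saker falcon; chromosome-level homology only (reference coordinates
# unknown, "NA").  Chicken unit set: GGA4 q+p is a single unit "4".
# Target chromosome numbering follows the published assignments where they
# are stated (FCH3/FCH5 carry the GGA1 halves, FCH6 a GGA3 half, FCH7/FCH10
# the GGA5 halves); remaining numbers are by approximate size and are not
# asserted by any downstream count.
tgt_chrom	tgt_start	tgt_end	ref_unit	ref_start	ref_end	strand	note
FCH1	NA	NA	2	NA	NA	+	GGA2 half (centric fission)
FCH1	NA	NA	21	NA	NA	+	microchromosome fused between GGA2 and GGA23 homologs
FCH1	NA	NA	23	NA	NA	+	fused microchromosome
FCH2	NA	NA	2	NA	NA	+	other GGA2 half
FCH2	NA	NA	28	NA	NA	+	fused microchromosome adjoining GGA2 and GGA14 homologs
FCH2	NA	NA	14	NA	NA	+	fused microchromosome adjoining GGA12 and GGA28 homologs
FCH2	NA	NA	12	NA	NA	+	fused microchromosome
FCH3	NA	NA	1	NA	NA	+	GGA1 half; fission shared with zebra finch lineage
FCH4	NA	NA	4	NA	NA	+	GGA4 q-arm segment
FCH4	NA	NA	15	NA	NA	+	fused microchromosome adjoining GGA4q and GGA19 homologs
FCH4	NA	NA	19	NA	NA	+	fused microchromosome adjoining GGA15 and GGA18 homologs
FCH4	NA	NA	18	NA	NA	+	fused microchromosome
FCH5	NA	NA	1	NA	NA	+	GGA1 half
FCH6	NA	NA	3	NA	NA	+	GGA3 half
FCH7	NA	NA	5	NA	NA	+	GGA5 half
FCH7	NA	NA	10	NA	NA	+	fused microchromosome
FCH8	NA	NA	6	NA	NA	+	fused with GGA17 homolog
FCH8	NA	NA	17	NA	NA	+	fused microchromosome
FCH9	NA	NA	7	NA	NA	+	fused with GGA13 homolog
FCH9	NA	NA	13	NA	NA	+	fused microchromosome
FCH10	NA	NA	5	NA	NA	+	GGA5 half
FCH10	NA	NA	20	NA	NA	+	fused microchromosome
FCH11	NA	NA	3	NA	NA	+	GGA3 half
FCH12	NA	NA	8	NA	NA	+	intact homolog
FCH13	NA	NA	9	NA	NA	+	intact homolog
FCH14	NA	NA	4	NA	NA	+	GGA4 p-arm segment as its own microchromosome
FCH15	NA	NA	11	NA	NA	+	intact microchromosome
FCH16	NA	NA	22	NA	NA	+	intact microchromosome
FCH17	NA	NA	24	NA	NA	+	intact microchromosome
FCH18	NA	NA	26	NA	NA	+	intact microchromosome
FCH19	NA	NA	27	NA	NA	+	intact microchromosome
FCHZ	NA	NA	Z	NA	NA	+	intact sex chromosome
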