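{
 "notes": "Published in-frame deletion designs for the two mad cyclase genes and the tetronomycin-cluster VstJ-like cyclase homologue, with the wild-type screening-PCR product sizes. The mad10 coding length (1404 nt) is the originally annotated frame; the revised protein (packaged FASTA) adds 15 codons, 3*(482-15+1) = 1404. The original screening-gel legend for the mad31 design reads 'Delta-tsn15 mutant: 689 bp' where context implies the mad31 mutant; recorded as printed.",
 "designs": [
  {"gene_id": "mad10", "gene_cds_length_nt": 1404, "deleted_length_nt": 906, "wt_amplicon_nt": 1913,
   "printed_mutant_amplicon_nt": 1007, "printed_mutant_label": "Δmad10 mutant"},
  {"gene_id": "mad31", "gene_cds_length_nt": 561, "deleted_length_nt": 291, "wt_amplicon_nt": 980,
   "printed_mutant_amplicon_nt": 689, "printed_mutant_label": "Δtsn15 mutant (as printed; context implies Δmad31)"},
  {"gene_id": "tmn8", "gene_cds_length_nt": 573, "deleted_length_nt": 573, "wt_amplicon_nt": 971,
   "printed_mutant_amplicon_nt": 398, "printed_mutant_label": "Δtmn8 mutant"}
 ]
}
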