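{
 "cluster_id": "mad",
 "notes": "Canonical architecture of the tetromadurin (mad) cluster: seven PKS multienzymes carrying one loading plus 14 extension modules, and the tailoring/precursor genes with their functional labels. Extender assignment per module follows the stereochemistry and side-methyl arguments where they pin a module (propionate at 4, 7, 11, 12; acetate at 2, 8, 14; methoxymalonate at 13); the side-methyl numbering constrains one propionate in each of {1,3}, {5,6} and {9,10}, resolved here toward modules 1, 6 and 10 so the tally is 6 acetate / 8 propionate (counting the loading unit) / 1 methoxymalonate. The loading AT carries the relaxed hybrid HASH motif.",
 "modules": [
  {"module_index": "LM", "gene_id": "madAI", "domains": [
    {"kind": "KS", "ks_residue": "Q"},
    {"kind": "AT", "at_motif": "HASH"},
    {"kind": "ACP"}]},
  {"module_index": "1", "gene_id": "madAI", "domains": [
    {"kind": "KS", "ks_residue": "C"},
    {"kind": "AT", "at_motif": "VASH"},
    {"kind": "DH", "ygp_tyr": true, "catalytic_asp": true},
    {"kind": "KR", "catalytic_tyr": true, "ldd": true, "pro_at_tyr_plus2": false, "nadph_deletion": false},
    {"kind": "ACP"}]},
  {"module_index": "2", "gene_id": "madAI", "domains": [
    {"kind": "KS", "ks_residue": "C"},
    {"kind": "AT", "at_motif": "HAFH"},
    {"kind": "DH", "ygp_tyr": true, "catalytic_asp": true},
    {"kind": "ER", "key_tyr": true},
    {"kind": "KR", "catalytic_tyr": true, "ldd": true, "pro_at_tyr_plus2": false, "nadph_deletion": false},
    {"kind": "ACP"}]},
  {"module_index": "3", "gene_id": "madAII", "domains": [
    {"kind": "KS", "ks_residue": "C"},
    {"kind": "AT", "at_motif": "TAFH"},
    {"kind": "DH", "ygp_tyr": true, "catalytic_asp": true},
    {"kind": "KR", "catalytic_tyr": true, "ldd": true, "pro_at_tyr_plus2": false, "nadph_deletion": false},
    {"kind": "ACP"}]},
  {"module_index": "4", "gene_id": "madAII", "domains": [
    {"kind": "KS", "ks_residue": "C"},
    {"kind": "AT", "at_motif": "YASH"},
    {"kind": "DH", "ygp_tyr": true, "catalytic_asp": true},
    {"kind": "ER", "key_tyr": false},
    {"kind": "KR", "catalytic_tyr": true, "ldd": true, "pro_at_tyr_plus2": false, "nadph_deletion": false},
    {"kind": "ACP"}]},
  {"module_index": "5", "gene_id": "madAIII", "domains": [
    {"kind": "KS", "ks_residue": "C"},
    {"kind": "AT", "at_motif": "VAFH"},
    {"kind": "DH", "ygp_tyr": false, "catalytic_asp": true},
    {"kind": "KR", "catalytic_tyr": true, "ldd": true, "pro_at_tyr_plus2": false, "nadph_deletion": false},
    {"kind": "ACP"}]},
  {"module_index": "6", "gene_id": "madAIII", "domains": [
    {"kind": "KS", "ks_residue": "C"},
    {"kind": "AT", "at_motif": "WASH"},
    {"kind": "DH", "ygp_tyr": true, "catalytic_asp": true},
    {"kind": "KR", "catalytic_tyr": true, "ldd": true, "pro_at_tyr_plus2": false, "nadph_deletion": false},
    {"kind": "ACP"}]},
  {"module_index": "7", "gene_id": "madAIV", "domains": [
    {"kind": "KS", "ks_residue": "C"},
    {"kind": "AT", "at_motif": "YASH"},
    {"kind": "KR", "catalytic_tyr": true, "ldd": true, "pro_at_tyr_plus2": false, "nadph_deletion": false},
    {"kind": "ACP"}]},
  {"module_index": "8", "gene_id": "madAIV", "domains": [
    {"kind": "KS", "ks_residue": "C"},
    {"kind": "AT", "at_motif": "YAFH"},
    {"kind": "DH", "ygp_tyr": true, "catalytic_asp": true},
    {"kind": "ER", "key_tyr": true},
    {"kind": "KR", "catalytic_tyr": true, "ldd": true, "pro_at_tyr_plus2": false, "nadph_deletion": false},
    {"kind": "ACP"}]},
  {"module_index": "9", "gene_id": "madAV", "domains": [
    {"kind": "KS", "ks_residue": "C"},
    {"kind": "AT", "at_motif": "HAFH"},
    {"kind": "DH", "ygp_tyr": true, "catalytic_asp": true},
    {"kind": "KR", "catalytic_tyr": true, "ldd": true, "pro_at_tyr_plus2": false, "nadph_deletion": false},
    {"kind": "ACP"}]},
  {"module_index": "10", "gene_id": "madAV", "domains": [
    {"kind": "KS", "ks_residue": "C"},
    {"kind": "AT", "at_motif": "YASH"},
    {"kind": "DH", "ygp_tyr": true, "catalytic_asp": true},
    {"kind": "KR", "catalytic_tyr": true, "ldd": true, "pro_at_tyr_plus2": false, "nadph_deletion": false},
    {"kind": "ACP"}]},
  {"module_index": "11", "gene_id": "madAVI", "domains": [
    {"kind": "KS", "ks_residue": "C"},
    {"kind": "AT", "at_motif": "VASH"},
    {"kind": "DH", "ygp_tyr": true, "catalytic_asp": true},
    {"kind": "ER", "key_tyr": false},
    {"kind": "KR", "catalytic_tyr": true, "ldd": true, "pro_at_tyr_plus2": false, "nadph_deletion": false},
    {"kind": "ACP"}]},
  {"module_index": "12", "gene_id": "madAVI", "domains": [
    {"kind": "KS", "ks_residue": "C"},
    {"kind": "AT", "at_motif": "YASH"},
    {"kind": "DH", "ygp_tyr": true, "catalytic_asp": true},
    {"kind": "KR", "catalytic_tyr": false, "ldd": true, "pro_at_tyr_plus2": false, "nadph_deletion": true},
    {"kind": "ACP"}]},
  {"module_index": "13", "gene_id": "madAVI", "domains": [
    {"kind": "KS", "ks_residue": "C"},
    {"kind": "AT", "at_motif": "YASH"},
    {"kind": "DH", "ygp_tyr": true, "catalytic_asp": true},
    {"kind": "KR", "catalytic_tyr": true, "ldd": true, "pro_at_tyr_plus2": false, "nadph_deletion": false},
    {"kind": "ACP"}]},
  {"module_index": "14", "gene_id": "madAVII", "domains": [
    {"kind": "KS", "ks_residue": "C"},
    {"kind": "AT", "at_motif": "HAFH"},
    {"kind": "KR", "catalytic_tyr": false, "ldd": true, "pro_at_tyr_plus2": false, "nadph_deletion": false},
    {"kind": "ACP"}]}
 ],
 "tailoring_genes": [
  {"gene_id": "mad1", "product_label": "regulator"},
  {"gene_id": "mad2", "product_label": "regulator"},
  {"gene_id": "mad3", "product_label": "other"},
  {"gene_id": "mad4", "product_label": "other"},
  {"gene_id": "mad6", "product_label": "other"},
  {"gene_id": "mad7", "product_label": "FkbH-like"},
  {"gene_id": "mad8", "product_label": "ACP"},
  {"gene_id": "mad10", "product_label": "PyrE3-like-cyclase"},
  {"gene_id": "mad11", "product_label": "dehydrogenase"},
  {"gene_id": "mad12", "product_label": "ACP"},
  {"gene_id": "mad13", "product_label": "dehydrogenase"},
  {"gene_id": "mad14", "product_label": "FkbH-like"},
  {"gene_id": "mad15", "product_label": "O-methyltransferase"},
  {"gene_id": "mad16", "product_label": "FabH-like"},
  {"gene_id": "mad17", "product_label": "acyltransferase(Agg4-like)"},
  {"gene_id": "mad18", "product_label": "dehydratase(Agg5-like)"},
  {"gene_id": "mad20", "product_label": "other"},
  {"gene_id": "mad25", "product_label": "transporter"},
  {"gene_id": "mad26", "product_label": "transporter"},
  {"gene_id": "mad27", "product_label": "regulator"},
  {"gene_id": "mad29", "product_label": "P450"},
  {"gene_id": "mad30", "product_label": "P450"},
  {"gene_id": "mad31", "product_label": "VstJ-like-cyclase"},
  {"gene_id": "madB", "product_label": "epoxide-hydrolase"},
  {"gene_id": "madC", "product_label": "epoxidase"}
 ]
}
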