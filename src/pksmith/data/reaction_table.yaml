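# Post-assembly tailoring pathway for the polyether tetronate produced by the
# mad cluster (tetromadurin).  Each step carries the genes it requires, the
# cluster capability that licenses it, a signed element delta applied to the
# running molecular formula, and its prerequisites.
#
# Roman-numeral step ids follow the pathway convention used for this compound
# family: precursor-supply steps (II-VIII) are capability gates rather than
# reactions on the chain and therefore do not appear here.
#
# The tetronate-formation delta (IX) is defined as the exact element
# difference between the linear free-acid chain plus a glycerate unit and the
# post-condensation intermediate: +C3H2O2 (three glycerate carbons arrive; the
# Claisen condensation and lactonisation shed the waters).  It is
# cross-validated by the C42H64O12 endpoint.
#
# Hydration of the oxadecalin (XVI) and tetrahydropyran formation (XVII) are
# fused into one formula-neutral composite step: whether the cyclase acts on
# the ketone or the hemiacetal form is left open, and the two routes are
# formula-identical.
version: 1
final_product_label: "tetromadurin (1)"
steps:
  - id: IX
    name: tetronate formation and chain release (FabH-like condensation with glyceryl-ACP)
    genes: [mad16, mad7, mad8]
    capability: has_glycerate_operon
    delta: {C: 3, H: 2, O: 2}
    prerequisites: []
    site: "C1-C3 + glycerate carbons C39-C41"
  - id: XII
    name: acetylation of the C41 hydroxyl
    genes: [mad17]
    capability: has_glycerate_operon
    delta: {C: 2, H: 2, O: 1}
    prerequisites: []
    site: "C41"
  - id: XIII
    name: acetate elimination forming the exocyclic double bond
    genes: [mad18]
    capability: has_glycerate_operon
    delta: {C: -2, H: -4, O: -2}
    prerequisites: [XII]
    site: "C40-C41"
  - id: X
    name: double epoxidation of the E double bonds
    genes: [madC]
    capability: has_epoxidase_hydrolase_pair
    delta: {O: 2}
    prerequisites: []
    site: "C24-C25 and C28-C29"
  - id: XI
    name: epoxide-opening cascade forming the two tetrahydrofuran rings
    genes: [madB]
    capability: has_epoxidase_hydrolase_pair
    delta: {}
    prerequisites: [X]
    site: "C21-C24 and C25-C28"
  - id: XIV
    name: hydroxylation of C36 (first cytochrome P450)
    genes: [mad29]
    capability: p450
    delta: {O: 1}
    prerequisites: []
    site: "C36"
  - id: XV
    name: "[4+2] cycloaddition forming the oxadecalin (cyclohexane precursor)"
    genes: [mad10]
    capability: pyrE3_like_cyclase
    delta: {}
    prerequisites: [XI]
    site: "oxadecalin core"
  - id: XVII
    name: hydration and tetrahydropyran formation (composite, formula-neutral)
    genes: [mad31]
    capability: vstJ_like_cyclase
    delta: {}
    prerequisites: [XV]
    site: "tetrahydropyran ring; dismantles the oxadecalin"
  - id: XVIII
    name: hydroxylation of C38 (second cytochrome P450)
    genes: [mad30]
    capability: p450_pair
    delta: {O: 1}
    prerequisites: [XV]   # configurable: may instead require XVII
    site: "C38"
# genes whose loss removes an extender unit's supply entirely
extender_supply:
  methoxymalonate: [mad11, mad12, mad13, mad14, mad15]
# product labels keyed by the exact blocked-step set
label_rules:
  - blocked: [XV, XVII, XVIII]
    label: "T-17 candidate (15): uncyclised, lacking one primary hydroxyl"
  - blocked: [XVIII]
    label: "C38-deoxy candidate (16)"
  - blocked: [XVII]
    label: "oxadecalin-derived intermediate (not experimentally observed)"
  - blocked: [XVII, XVIII]
    label: "oxadecalin-derived intermediate, C38-deoxy (not experimentally observed)"
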