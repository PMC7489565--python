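>mad10_revised PyrE3-like [4+2] cyclase, start revised 15 codons upstream of the original annotation; residues 1-15 are the added peptide
MSDSVVIIGAGPVGLMLAHELALAGVRTVVIERRPEIDARTVSGLIHERSVELLEQRGLM
EQIRREDGEPLVWDRLHFASFWLDMSELAKTDHSVVLLQTRIQRLLSDRAAARGVHILRR
HELVGLSQDEDGVTARVHSPLGEEEIRCGYLVGCDGEDSAVRELAGFAVTRSGPSWYGLL
ADVGSYAGPVGAGSFHEGGMFGQFGDASTMFRLMTIEIGVEAPPAEQPVTLEEVRASIER
ITGERPTVEEPLWLHRHGNVTILADEYRNGRVFLAGDAAHFQFHPAGHAVTIGLQDAVNL
GWKLAAKLQGWAPAGLLDSYDAERRPYGRRACVYGRAQMALLDTADGPSALREVFGELLD
HDVVNRHLVRAATDARYPMGQAEDLVGRRVPLVSLSTPGGEVPVAETLHAARGVLLDLSG
GTEPPDVTGWKDRVDVVAAEPTPEIPASAVLVRPDGHIAWAGEAVGEGLHTALAAWFGEP
AA
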