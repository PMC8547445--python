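>PFS promoter-free sequence, inert 100-nt replacement for knocked-out promoter regions
CATTACTCGCATCCATTCTCAGGCTGTCTCGTCTCGTCTCGCTGGGAGTTCGTAGACGGAAACAAACGCA
GAATCCAAGCGCACTGAAGGTCCTCAATCG
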