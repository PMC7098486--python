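>sp|P0CG48|UBC_HUMAN ubiquitin monomer (residues 1-76)
MQIFVKTLTGKTITLEVEPSDTIENVKAKIQDKEGIPPDQQRLIFAGKQLEDGRTLSDYN
IQKESTLHLVLRLRGG
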