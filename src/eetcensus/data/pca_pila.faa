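>GSU1496_PilA Geobacter sulfurreducens PCA major pilin PilA preprotein (public database sequence)
MLQKLRNRKGFTLIELLIVVAIIGILAAIAIPQFSAYRVKAYNSAASSDLRNLKTALESAFADDQTYPPES
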