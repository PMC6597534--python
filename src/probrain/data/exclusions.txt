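# Specimens excluded from the final PGLS refit (n = 19 retained).
# Three taxa are excluded outright; the conspecific choices among
# P. antiquus, E. maximus and L. africana are the largest-|normalized
# residual| specimens of those species under the full-data lambda-model fit
# (the published account names the species but not which individuals).
Moeritherium_lyonsi_1
Palaeomastodon_beadnelli_1
Palaeoloxodon_falconeri_1
Palaeoloxodon_antiquus_1
Elephas_maximus_4
Loxodonta_africana_2
Loxodonta_africana_3
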