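# Node-age and fossil-tip-age calibrations for the packaged consensus tree of
# Proboscidea, in Ma before present.  Two internal ages are fixed by the study
# design (Elephantimorpha last common ancestor 26 Ma, late Oligocene;
# Elephantoidea last common ancestor 20 Ma, early Miocene).  The remaining ages
# are approximate defaults taken from the cited divergence-time literature and
# the stratigraphic ranges of the fossil specimens; they may be edited and the
# tree rebuilt with probrain.synthetic.build_species_tree.
#
# Internal nodes (clade name = age in Ma)
Proboscidea=40
Elephantiformes=35
Elephantimorpha=26
Mammutida=15
Elephantoidea=20
Elephantidae=8
ElephasLoxodonta=6
Palaeoloxodon=1
Mammuthus=3.5
MammuthusCP=1.5
# Tips (taxon = age of the fossil tip in Ma; extant taxa at 0)
Moeritherium_lyonsi=36
Palaeomastodon_beadnelli=33
Mammut_americanum=0.01
Zygolophodon_borsoni=3.5
Stegodon_insignis=8
Mammuthus_primigenius=0.01
Mammuthus_meridionalis=1.5
Mammuthus_columbi=0.01
Palaeoloxodon_antiquus=0.1
Palaeoloxodon_falconeri=0.5
Elephas_maximus=0
Loxodonta_africana=0
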