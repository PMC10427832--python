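"""Published reference data for the Virunga volcanoes bird community.

Body masses (grams) of the within-family species pairs analysed in the
montane-forest point-count study of the Virunga volcanoes (Albertine Rift),
as printed in its pair-metrics table.  Families with two or more modelled
species are listed; masses feed the family body-size coefficient of
variation, one of the niche dimensions.
"""

FAMILY_MASSES_G = {
    "Musophagidae": {"T. schuetti": 235.0, "R. johnstoni": 240.0},
    "Nectariniidae": {
        "C. regius": 6.58, "C. stuhlmanni": 8.5, "C. venustus": 6.56,
        "C. alinae": 12.56, "H. collaris": 6.98, "N. johnstoni": 15.16,
    },
    "Lybiidae": {
        "P. bilineatus": 13.1, "P. coryphaeus": 10.7, "T. purpuratus": 76.1,
    },
    "Cisticolidae": {
        "A. porphyrolaema": 8.39, "A. personata": 11.0, "C. chubbi": 16.03,
        "O. ruwenzorii": 9.9, "P. bairdii": 13.4,
    },
    "Phylloscopidae": {"P. laetus": 9.54, "P. umbrovirens": 8.6},
    "Malaconotidae": {
        "D. gambensis": 31.9, "L. aethiopicus": 49.44, "L. luehderi": 42.9,
        "L. poensis": 44.9, "T. dohertyi": 35.02,
    },
    "Cuculidae": {
        "C. monachus": 201.31, "C. klaas": 27.37, "C. solitarius": 76.73,
    },
    "Pycnonotidae": {
        "E. latirostris": 26.2, "A. nigriceps": 32.8, "P. barbatus": 32.1,
    },
    "Columbidae": {
        "C. arquatrix": 400.0, "S. lugens": 155.0, "S. semitorquata": 176.0,
    },
    "Platysteiridae": {"B. diops": 12.7, "B. molitor": 11.64},
    "Ploceidae": {"P. alienus": 22.2, "P. baglafecht": 31.6},
    "Fringillidae": {"C. frontalis": 12.3, "C. gularis": 16.0},
    "Estrildidae": {"E. astrild": 8.29, "E. kandti": 7.48},
    "Acrocephalidae": {"I. natalensis": 11.7, "I. similis": 11.1},
    "Muscicapidae": {
        "M. fisheri": 23.4, "B. comitatus": 14.1, "C. archeri": 22.8,
        "P. stellata": 18.6,
    },
}
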