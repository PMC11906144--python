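"""A curated list of common odorant-like structures (isomeric SMILES).

Used by the synthetic-study generator so that molecular featurization runs on
chemistry that resembles a real fragrance screen: esters, terpenoids,
aldehydes, alcohols, ketones, lactones, pyrazines, phenols and a few
sulfur-bearing notes. Several entries carry stereocentres (menthol,
carvone, linalool enantiomers) so stereo-aware descriptors are exercised.
"""

ODORANT_SMILES: tuple[str, ...] = (
    # small esters (fruity)
    "CCOC(C)=O",                # ethyl acetate
    "CCCOC(C)=O",               # propyl acetate
    "CCCCOC(C)=O",              # butyl acetate
    "CCCCCOC(C)=O",             # amyl acetate
    "CC(C)COC(C)=O",            # isobutyl acetate
    "CC(C)CCOC(C)=O",           # isoamyl acetate
    "CCOC(=O)CC",               # ethyl propanoate
    "CCOC(=O)CCC",              # ethyl butanoate
    "CCOC(=O)CCCC",             # ethyl pentanoate
    "CCOC(=O)CCCCC",            # ethyl hexanoate
    "CCOC(=O)CCCCCCC",          # ethyl octanoate
    "COC(=O)CCC",               # methyl butanoate
    "COC(=O)CCCCC",             # methyl hexanoate
    "CCCCOC(=O)CCC",            # butyl butanoate
    "CCCCCCOC(C)=O",            # hexyl acetate
    "CC(C)(C)CC(C)OC(C)=O",     # 4,4-dimethylpentan-2-yl acetate
    "COC(=O)c1ccccc1",          # methyl benzoate
    "CCOC(=O)c1ccccc1",         # ethyl benzoate
    "COC(=O)c1ccccc1O",         # methyl salicylate
    "CC(=O)OCc1ccccc1",         # benzyl acetate
    "CCOC(=O)Cc1ccccc1",        # ethyl phenylacetate
    "COC(=O)CCc1ccccc1",        # methyl 3-phenylpropanoate
    "CC(=O)OCCc1ccccc1",        # phenethyl acetate
    "CCOC(=O)C(C)C",            # ethyl isobutyrate
    "CCOC(=O)C=C",              # ethyl acrylate
    "CCOC(=O)/C=C/C",           # ethyl crotonate
    "COC(=O)/C=C/c1ccccc1",     # methyl cinnamate
    # aldehydes (green, citrus, fatty)
    "CCCCCC=O",                 # hexanal
    "CCCCCCC=O",                # heptanal
    "CCCCCCCC=O",               # octanal
    "CCCCCCCCC=O",              # nonanal
    "CCCCCCCCCC=O",             # decanal
    "CCCCC/C=C/C=O",            # trans-2-octenal
    "CC/C=C\\CC/C=C/C=O",       # 2,6-nonadienal
    "O=Cc1ccccc1",              # benzaldehyde
    "COc1cc(C=O)ccc1O",         # vanillin
    "O=CCc1ccccc1",             # phenylacetaldehyde
    "O=C/C=C/c1ccccc1",         # cinnamaldehyde
    "CC(C)Cc1ccc(C(C)C=O)cc1",  # cyclamen aldehyde relative
    "O=CC(C)Cc1ccccc1",         # 2-methyl-3-phenylpropanal
    # alcohols
    "CCO",                      # ethanol
    "CCCCO",                    # butanol
    "CCCCCCO",                  # hexanol
    "CCCCCCCCO",                # octanol
    "CC/C=C\\CCO",              # cis-3-hexenol (leaf alcohol)
    "OCc1ccccc1",               # benzyl alcohol
    "OCCc1ccccc1",              # phenethyl alcohol
    "CC(C)CCO",                 # isoamyl alcohol
    "CCCCC(C)O",                # 2-heptanol
    "CCCCCC(O)C=C",             # 1-octen-3-ol (mushroom)
    # terpenoids, with stereo where it matters
    "CC(C)=CCC/C(C)=C/CO",      # geraniol
    "CC(C)=CCC/C(C)=C\\CO",     # nerol
    "CC(C)=CCCC(C)CCO",         # citronellol
    "CC(C)=CCC[C@@](C)(O)C=C",  # (R)-linalool
    "CC(C)=CCC[C@](C)(O)C=C",   # (S)-linalool
    "CC(C)=CCC/C(C)=C/C=O",     # citral (geranial)
    "CC1=CC[C@@H](C(C)C)CC1",   # (R)-alpha-phellandrene-like menthene
    "CC1=CC[C@H](CC1)C(C)=C",   # (S)-limonene
    "CC1=CC[C@@H](CC1)C(C)=C",  # (R)-limonene
    "C[C@@H]1CC[C@H](C(C)C)[C@@H](O)C1",  # l-menthol
    "C[C@H]1CC[C@@H](C(C)C)[C@H](O)C1",   # d-menthol
    "C[C@@H]1CC[C@H](C(C)C)C(=O)C1",      # menthone
    "CC1=CC[C@H](CC1=O)C(C)=C",           # (R)-carvone
    "CC1=CC[C@@H](CC1=O)C(C)=C",          # (S)-carvone
    "CC1(C)[C@@H]2CC[C@@]1(C)C(=O)C2",    # camphor
    "CC1(C)[C@@H]2CC[C@@H](C2)C1=C",      # camphene-like bicyclic
    "CC(C)C1=CC=C(C)CC1=O",     # cryptone relative
    "CC(C)c1ccc(C)cc1O",        # thymol
    "Cc1ccc(C(C)C)cc1O",        # carvacrol
    "CC(C)c1ccc(C)cc1",         # p-cymene
    "CC(C)=CCCC(C)=CC=O",       # citral mixture isomer
    "CC1=CCC2CC1C2(C)C",        # alpha-pinene skeleton
    "CC(C)C12CCC(C)(CC1)O2",    # eucalyptol-like ether
    # ketones
    "CCCCCC(C)=O",              # 2-heptanone
    "CCCCCCC(C)=O",             # 2-octanone
    "CCCCCCCC(C)=O",            # 2-nonanone
    "CCCC(=O)CC",               # 3-hexanone
    "CCCCC(=O)CC",              # 3-heptanone
    "CCCCCC(=O)CC",             # 3-octanone
    "CC(=O)c1ccccc1",           # acetophenone
    "CC(=O)CC(C)(C)c1ccccc1",   # raspberry-ketone relative
    "CC(=O)CCc1ccc(O)cc1",      # raspberry ketone
    "O=C1CCCc2ccccc21",         # 1-tetralone
    "CC1=CC(=O)CC(C)(C)C1",     # isophorone
    "CC(=O)/C=C/c1ccccc1",      # benzylideneacetone
    # lactones (coconut, peach)
    "CCCCCC1CCC(=O)O1",         # gamma-nonalactone
    "CCCCCCC1CCC(=O)O1",        # gamma-decalactone
    "CCCCC1CCCC(=O)O1",         # delta-nonalactone
    "O=C1CCOc2ccccc21",         # dihydrocoumarin
    "O=c1ccc2ccccc2o1",         # coumarin
    # phenols / ethers (smoky, spicy, anise)
    "COc1ccccc1",               # anisole
    "COc1ccc(C=C)cc1",          # 4-methoxystyrene
    "COc1ccc(CC=C)cc1",         # estragole
    "COc1ccc(/C=C/C)cc1",       # anethole
    "COc1cc(CC=C)ccc1O",        # eugenol
    "COc1cc(/C=C/C)ccc1O",      # isoeugenol
    "Cc1ccc(O)cc1",             # p-cresol
    "CCc1ccc(O)cc1",            # 4-ethylphenol
    "COc1ccccc1O",              # guaiacol
    "Cc1ccc(C)c(O)c1",          # 2,4-xylenol relative
    # pyrazines / heteroaromatics (roasted, nutty, green pepper)
    "Cc1cnccn1",                # 2-methylpyrazine
    "Cc1cncc(C)n1",             # 2,6-dimethylpyrazine
    "Cc1cnc(C)cn1",             # 2,5-dimethylpyrazine
    "CCc1cnccn1",               # 2-ethylpyrazine
    "COc1cnccn1",               # methoxypyrazine
    "COc1cnc(C(C)C)cn1",        # isopropyl methoxypyrazine relative
    "CCc1cncc(C)n1",            # ethyl methyl pyrazine
    "Cc1ccco1",                 # 2-methylfuran
    "Cc1ccc(C=O)o1",            # 5-methylfurfural
    "O=Cc1ccco1",               # furfural
    "OCc1ccco1",                # furfuryl alcohol
    "CC(=O)c1ccco1",            # 2-acetylfuran
    "CC(=O)c1cccs1",            # 2-acetylthiophene
    "Cc1ccncc1",                # 4-methylpyridine
    "CC1=C(C)C(=O)C(O)=CO1",    # maltol-like pyranone (written open)
    # sulfur notes
    "CCS",                      # ethanethiol
    "CCCS",                     # propanethiol
    "CC(C)CS",                  # isobutyl mercaptan
    "CSSC",                     # dimethyl disulfide
    "CSC",                      # dimethyl sulfide
    "CCSSCC",                   # diethyl disulfide
    "SCC1CCOC1",                # thiol-tetrahydrofuran relative
    "CSCCCO",                   # methionol relative
    # acids (cheesy, sweaty)
    "CCCC(=O)O",                # butyric acid
    "CCC(C)C(=O)O",             # 2-methylbutyric acid
    "CC(C)CC(=O)O",             # isovaleric acid
    "CCCCCC(=O)O",              # hexanoic acid
    "CCCCCCCC(=O)O",            # octanoic acid
    "OC(=O)/C=C/c1ccccc1",      # cinnamic acid
    # musks / large ring stand-ins and miscellany
    "O=C1CCCCCCCCCCCCCCC1",     # cyclopentadecanone (exaltone)
    "O=C1OCCCCCCCCCCCCCC1",     # pentadecanolide
    "CC(C)(C)c1ccc(CCC=O)cc1",  # bourgeonal relative
    "CC(C)(C)c1ccc(C(C)CC=O)cc1",  # lily aldehyde relative
    "CC(C)(C)C1CCC(C)(CC1)OC(C)=O",  # vertenex-like acetate
    "CCC(C)(O)c1ccccc1",        # phenyl tertiary alcohol
    "CC(O)c1ccccc1",            # 1-phenylethanol
    "Cc1ccccc1C",               # o-xylene
    "Cc1ccccc1",                # toluene (solvent note)
    "c1ccc2ccccc2c1",           # naphthalene (mothball)
    "CC(C)CC=O",                # isovaleraldehyde
    "CC(C)C=O",                 # isobutyraldehyde
    "CCC(C)C=O",                # 2-methylbutanal
    "CC(=O)C(C)=O",             # diacetyl (buttery)
    "CC(O)C(C)=O",              # acetoin
    "CCCCC(CC)C=O",             # 2-ethylhexanal
    "OCC(CC)CCCC",              # 2-ethylhexanol
)
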