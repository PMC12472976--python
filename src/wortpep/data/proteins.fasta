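>P06470 B1-hordein (Hordeum vulgare)
MKTFLIFALLAIAATSTIAQQQPFPQQPIPQQPQPYPQQPQPYPQQPFPPQQPFPQQPVP
QQPQPYPQQPFPPQQPFPQQPPFWQQKPFPQQPPFGLQQPILSQQQPCTPQQTPLPQGQL
YQTLLQLQIQYVHPSILQQLNPCKVFLQQQCSPVPVPQRIARSQMLQQSSCHVLQQQCCQ
QLPQIPEQFRHEAIRAIVYSIFLQEQPQQLVEGVSQPQQQLWPQQVGQCSFQQPQPQQVG
QQQQVPQSAFLQPHQIAQLEATTSIALRTLPMMCSVNVPLYRILRGVGPSVGV
>P06472 C-hordein (Hordeum vulgare)
QPQQSYPVQPQQPFPQPQPVPQQRPQQASPLQPQQPFPQGSEQIIPQQPFPLQPQPFPQQ
PQQPLPQPQQPFRQQAELIIPQQPQQPLPLQPHQPYTQQTIWSMV
>I6SW23 D-hordein (Hordeum vulgare)
MAKRLVLFVAVIVALVALTTAEREINGNNIFLDSRSRQLQCERELQESSLEACRRVVDQQ
LVGQLPWSTGLQMQCCQQLRDVSPECRPVALSQVVRQYEQQTEVPSKGGSFYPGGTAPPL
QQGGWWGTSVKWYYPDQTSSQQSWQGQQGYHQSVTSSQQPGQGQQGSYPGSTFPQQPGQG
QQPGQRQPWSYPSATFPQQPGQGQGQQGYYPGATSLLQPGQGQQGPYQSATSPQQPGQGQ
GQQETYPIATSPHQPGQWQQPGQGQQGYYPSVTSPQQSGQGQQGYPSTTSPQQSGQGQQL
GQGQQPGQGQQGYPSATFPQQPGQWQQGSYPSTTSPQQSGQGQQGYNPSGTSTQQPGQVQ
QLGQGQQGYYPIATSPQQPGQGQQLGQGQQPGHGQQLVQGQQQGQGQQGHYPSMTSPHQT
GQGQKGYYPSAISPQQSGQGQQGYQPSGASSQGSVQGACQHSTSSPQQQAQGCQASSPKQ
GLGSLYYPSGAYTQQKPGQGYNPGGTSPLHQQGGGFGGGLTTEQPQGGKQPFHCQQTTVS
PHQGQQTTVSPHQGQQTTVSPHQGQQTTVSPHQGQQTTVSPHQGQQTTVSPHQGQQTTVS
PHPGQQTTVSPHQGQQTTVSPHPGQQTTVSPHQGQQTTVSPHQGQQTTVSPHQGQQTTVS
PHQGQQTTVSPHQGQQPGEQPCGFPGQQTTVSLHHGQQSNELYYGSPYHVSVEQPSASLK
VAKAQQLAAQLPAMCRLEGGGGLLASQ
>A0A090CXP9 11S seed storage protein (Cannabis sativa)
MARSSTSLLCFTLFSLLLSHACFAQIEQMPQRSQRGGQQRQQHRWQSQCQFQRLNARQPN
RRVECEAGVSEYWDIQNTEDDELHCAGVETARHTIQRRGLLLPSFLNAPMMFYVIQGRGI
HGAVIPGCPETFERGTSSPSSRGYRSEGASSDEQHQKVREIKEGDMVAMPAGVADWVYNN
GDSPLVLIAFVDVGNQANQLDQFSRRFHLAGNPHREQKTQQQVRARSQSRSQLRRESGEQ
TPNGNIFSGFDTRILAESFNVDTELAHKLQNRDDMRERIVRVRGEDLQIIAPSRIQEEER
RHYSRDNGLEETFCTLRLRQNIDRPSQADIFNPRGGRLNTLNNYNLPILRFLQLTAERGV
LYKNGMMAPHFNLDSHSVIYVTRGSARLQVVDDNGRNVFDGELREGQIFVVPQNFAVVKK
ASAQGFEWIAVKTNDNAMRNPLAGKVSAMRAMPDDVLANAFQTSREQARRLKYGRDEISV
FSPSSQQTRYE
>A0A803Q1B3 Bifunctional protein (Cannabis sativa)
MESLVHLPRLLVAALAIFAVLITPVFGQVSTPCNASMISSFTPCMNFVTNSSSAGTSPTS
DCCNALKTLTSSGMDCLCLIVTGSVPFQVPINRSLAISLPRACNMAGVPVQCKATAAPIP
APAPASFGPALSPGDSPSSGLSPTGSSIPQPVSPALSPESDTTPLLTPPTTTGGSEAPTA
TTGSRSVLPPSAATTLYSSSSFLLFAMGCLVMELY
>A0A7J6FEU0 Storage protein (Cannabis sativa)
MANSHRSGLIKRSSDGARVVIGTIMGVIFGFFIGMSFPSVSLNKINLPSSLISSLDVAIT
DIHGSSISRSFEDNGPSNVPRIYVPTNPRGAELLPPGIIVSESDFYLRRLWGEPSEDLKK
KPKYLMTFTVGLDQKNNIDAAAKKLSEDFQIMLFHYDDRVTEWDEFEWSKDAIHVSVRKQ
TKWWYAKRFLHPDIVAAYEYIFIWDEDLGVENFNGDKYIELVKKHGLEISQPGLEPNNGL
TWEMTKRRGEQEVHKDAVERPGWCDNPRQPPCAAFVEIMAPVFSRKAWRCVWHMIQNDLV
HGWGLDFALRRCVEPAYEKIGVVDSQWIVHQTIPSLGNQASHHQYLLLFKQKISHSTGNS
EDGKAPWEGVRARCRNEWTEFQSRLNKADEEYFAHVGKG
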