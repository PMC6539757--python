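# Known designer fentanyl-like NPS for retro-prediction demos (no asserted values)
O=C(c1ccco1)N(c1ccccc1)C1CCN(CCc2ccccc2)CC1	furanylfentanyl
CC(=O)N(c1ccccc1)C1CCN(CCc2ccccc2)CC1	acetylfentanyl
C=CC(=O)N(c1ccccc1)C1CCN(CCc2ccccc2)CC1	acryloylfentanyl
O=C(c1ccc2c(c1)OCO2)N(c1ccccc1)C1CCN(CCc2ccccc2)CC1	benzodioxolefentanyl
O=C(C1CCCC1)N(c1ccccc1)C1CCN(CCc2ccccc2)CC1	cyclopentylfentanyl
O=C(C1CC1)N(c1ccccc1)C1CCN(CCc2ccccc2)CC1	cyclopropylfentanyl
O=C(C1CCCO1)N(c1ccccc1)C1CCN(CCc2ccccc2)CC1	tetrahydrofuranylfentanyl
O=C(c1ccoc1)N(c1ccccc1)C1CCN(CCc2ccccc2)CC1	3-furanylfentanyl
CCC(=O)N(c1ccccc1)C1CCN(CC(C)c2ccccc2)CC1	alpha-methylfentanyl
COCC(=O)N(c1ccccc1)C1CCN(CCc2ccccc2)CC1	methoxyacetylfentanyl
CCC(=O)N(c1ccc(F)cc1)C1CCN(CCc2ccccc2)CC1	4-fluorofentanyl
CCC(=O)N(c1ccccc1)C1CC(C)N(CCc2ccccc2)CC1	3-methylfentanyl
CC(C)C(=O)N(c1ccc(F)cc1)C1CCN(CCc2ccccc2)CC1	4-fluoroisobutyrylfentanyl
CC(C)C(=O)N(c1ccc(Cl)cc1)C1CCN(CCc2ccccc2)CC1	4-chloroisobutyrylfentanyl
CCCC(=O)N(c1ccc(OC)cc1)C1CCN(CCc2ccccc2)CC1	4-methoxybutyrylfentanyl
CCC(=O)N(c1ccccc1)C1CCN(CC(O)c2cccs2)CC1	beta-hydroxythiofentanyl
CC(C)C(=O)N(c1ccccc1)C1CCN(CCc2ccccc2)CC1	isobutyrylfentanyl
CC1(C)CC1(C)C(=O)N(c1ccccc1)C1CCN(CCc2ccccc2)CC1	tetramethylcyclopropylfentanyl
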