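# alias	preferred_label	source
# Covers every entity named in the packaged flesh-color reference tables.
AN1	AN1	protein-db
ANTHOCYANIN 1	AN1	protein-db
ANTHOCYANIDIN	ANTHOCYANIDIN	pathway-db
ANTHOCYANIN	ANTHOCYANIN	pathway-db
ASCORBIC ACID	ASCORBIC ACID	pathway-db
B-CAROTENE	BETA-CAROTENE	pathway-db
BETA-CAROTENE	BETA-CAROTENE	pathway-db
BCH	BETA-CAROTENE HYDROXYLASE	protein-db
B-CAROTENE HYDROXYLASE	BETA-CAROTENE HYDROXYLASE	protein-db
BETA-CAROTENE HYDROXYLASE	BETA-CAROTENE HYDROXYLASE	protein-db
BHLH	BHLH	protein-db
CAFFEIC ACID	CAFFEIC ACID	pathway-db
CAROTENE HYDROXYLASE	CAROTENE HYDROXYLASE	protein-db
CAROTENOID	CAROTENOID	pathway-db
CCD	CCD	protein-db
CHLOROGENIC ACID	CHLOROGENIC ACID	pathway-db
CHY	CHY	protein-db
CYANIDIN	CYANIDIN	pathway-db
EPOXIDES	EPOXIDES	pathway-db
ESSENTIAL AMINO ACIDS	ESSENTIAL AMINO ACIDS	pathway-db
GLYCOSIDES	GLYCOSIDES	pathway-db
LUTEIN	LUTEIN	pathway-db
LUTEIN-5,6-EPOXIDE	LUTEIN-5,6-EPOXIDE	pathway-db
MALVIDIN	MALVIDIN	pathway-db
NONEPOXIDE	NONEPOXIDE	pathway-db
OR	OR	protein-db
PELARGONIDIN	PELARGONIDIN	pathway-db
PEONIDIN	PEONIDIN	pathway-db
PETUNIDIN	PETUNIDIN	pathway-db
PF	PF	protein-db
PHENOLIC	PHENOLIC	pathway-db
PHENOLIC ACID	PHENOLIC ACID	pathway-db
PSY	PHYTOENE SYNTHASE	protein-db
PHYTOENE SYNTHASE	PHYTOENE SYNTHASE	protein-db
POLYPHENOL	POLYPHENOL	pathway-db
RECESSIVEZEP	ZEAXANTHIN EPOXIDASE	protein-db
RECESSIVE ZEP	ZEAXANTHIN EPOXIDASE	protein-db
TP	TP	protein-db
TUBERIGEN ACTIVATION COMPLEX	TUBERIGEN ACTIVATION COMPLEX	protein-db
VIOLAXANTHIN	VIOLAXANTHIN	pathway-db
VIOLAXANTHIN-LIKE CAROTENOID	VIOLAXANTHIN-LIKE CAROTENOID	pathway-db
XANTHOPHYLL	XANTHOPHYLL	pathway-db
ZEAXANTHIN	ZEAXANTHIN	pathway-db
ZEP	ZEAXANTHIN EPOXIDASE	protein-db
ZEAXANTHIN EPOXIDASE	ZEAXANTHIN EPOXIDASE	protein-db
DXS	DXS	protein-db
ABA	ABSCISIC ACID	pathway-db
ABSCISIC ACID	ABSCISIC ACID	pathway-db
AMINOCYCLOPROPANE-1-CARBOXYLIC ACID	AMINOCYCLOPROPANE-1-CARBOXYLIC ACID	pathway-db
1-AMINOCYCLOPROPANE-1-CARBOXYLIC ACID	AMINOCYCLOPROPANE-1-CARBOXYLIC ACID	pathway-db
CHLOROPHYLL	CHLOROPHYLL	pathway-db
ETHYLENE	ETHYLENE	pathway-db
FLAVONOID	FLAVONOID	pathway-db
FLAVONOL	FLAVONOL	pathway-db
HYDROXYCINNAMIC ACID	HYDROXYCINNAMIC ACID	pathway-db
LYCOPENE	LYCOPENE	pathway-db
LCY-E	LYCOPENE E-CYCLASE	protein-db
LYCOPENE E-CYCLASE	LYCOPENE E-CYCLASE	protein-db
PAL	PHENYLALANINE AMMONIA LYASE	protein-db
PHENYLALANINE AMMONIA LYASE	PHENYLALANINE AMMONIA LYASE	protein-db
NCED	9-CIS-EPOXYCAROTENOID DIOXYGENASE	protein-db
9-CIS-EPOXYCAROTENOID DIOXYGENASE	9-CIS-EPOXYCAROTENOID DIOXYGENASE	protein-db
9-CIS-NEOXANTHIN	9-CIS-NEOXANTHIN	pathway-db
FLAVONOID-3,5-HYDROXYLASE	FLAVONOID-3,5-HYDROXYLASE	protein-db
COLOR	COLOR	trait-ontology
FLESH	FLESH	trait-ontology
FLESH COLOR	FLESH COLOR	trait-ontology
FLESH TRAIT	FLESH TRAIT	trait-ontology
ORANGE FLESH COLOR	ORANGE FLESH COLOR	trait-ontology
TUBER COLOR	TUBER COLOR	trait-ontology
TUBER FLESH	TUBER FLESH	trait-ontology
TUBER FLESH COLOR	TUBER FLESH COLOR	trait-ontology
WHITE FLESH COLOR	WHITE FLESH COLOR	trait-ontology
YELLOW-ORANGE FLESH COLOR	YELLOW-ORANGE FLESH COLOR	trait-ontology
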