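# surface	preferred_label	entity_type
zeaxanthin epoxidase	ZEAXANTHIN EPOXIDASE	GENE_PROTEIN
ZEP	ZEAXANTHIN EPOXIDASE	GENE_PROTEIN
StZEP	ZEAXANTHIN EPOXIDASE	GENE_PROTEIN
beta-carotene hydroxylase	BETA-CAROTENE HYDROXYLASE	GENE_PROTEIN
b-carotene hydroxylase	BETA-CAROTENE HYDROXYLASE	GENE_PROTEIN
BCH1	BETA-CAROTENE HYDROXYLASE	GENE_PROTEIN
BCH2	BETA-CAROTENE HYDROXYLASE	GENE_PROTEIN
phytoene synthase	PHYTOENE SYNTHASE	GENE_PROTEIN
AN1	AN1	GENE_PROTEIN
StAN1	AN1	GENE_PROTEIN
lycopene e-cyclase	LYCOPENE E-CYCLASE	GENE_PROTEIN
phenylalanine ammonia lyase	PHENYLALANINE AMMONIA LYASE	GENE_PROTEIN
beta-carotene	BETA-CAROTENE	METABOLITE
b-carotene	BETA-CAROTENE	METABOLITE
β-carotene	BETA-CAROTENE	METABOLITE
zeaxanthin	ZEAXANTHIN	METABOLITE
violaxanthin	VIOLAXANTHIN	METABOLITE
carotenoid	CAROTENOID	METABOLITE
carotenoids	CAROTENOID	METABOLITE
anthocyanin	ANTHOCYANIN	METABOLITE
lutein	LUTEIN	METABOLITE
lycopene	LYCOPENE	METABOLITE
abscisic acid	ABSCISIC ACID	METABOLITE
flesh color	FLESH COLOR	TRAIT
tuber flesh color	TUBER FLESH COLOR	TRAIT
tuber color	TUBER COLOR	TRAIT
white flesh color	WHITE FLESH COLOR	TRAIT
orange flesh color	ORANGE FLESH COLOR	TRAIT
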