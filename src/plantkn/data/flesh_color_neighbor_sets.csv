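set_a,set_b,set_a_minus_set_b
AN1,anthocyanin,AN1
anthocyanidin,ascorbic acid,anthocyanidin
anthocyanin,b-carotene,carotene hydroxylase
ascorbic acid,b-carotene hydroxylase,cyanidin
b-carotene,bHLH,epoxides
b-carotene hydroxylase,caffeic acid,essential amino acids
bHLH,carotenoid,glycosides
caffeic acid,CCD,lutein
carotene hydroxylase,chlorogenic acid,"lutein-5,6-epoxide"
carotenoid,CHY,malvidin
CCD,Or,nonepoxide
chlorogenic acid,phenolic,pelargonidin
CHY,TP,peonidin
cyanidin,tuberigen activation complex,petunidin
epoxides,xanthophyll,Pf
essential amino acids,zeaxanthin,phenolic acid
glycosides,zeaxanthin epoxidase,phytoene synthase
lutein,,polyphenol
"lutein-5,6-epoxide",,recessiveZEP
malvidin,,violaxanthin
nonepoxide,,violaxanthin-like carotenoid
Or,,
pelargonidin,,
peonidin,,
petunidin,,
Pf,,
phenolic,,
phenolic acid,,
phytoene synthase,,
polyphenol,,
recessiveZEP,,
TP,,
tuberigen activation complex,,
violaxanthin,,
violaxanthin-like carotenoid,,
xanthophyll,,
zeaxanthin,,
zeaxanthin epoxidase,,
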