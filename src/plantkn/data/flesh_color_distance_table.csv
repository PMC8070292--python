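node,2000,2001,2002,2003,2004,2005,2006,2007,2008,2009,2010,2011,2012,2013,2014,2015,2016
CCD,x,x,x,x,3,3,3,3,3,3,1,1,1,1,1,1,1
CHY,x,x,x,x,x,x,x,2,2,2,1,1,1,1,1,1,1
DXS,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1
PSY,2,2,2,2,2,1,1,1,1,1,1,1,1,1,1,1,1
TP,x,x,x,x,x,x,x,x,x,3,3,2,2,2,2,2,1
abscisic acid,x,x,4,2,2,2,2,2,2,1,1,1,1,1,1,1,1
aminocyclopropane-1-carboxylic acid,x,x,x,x,x,5,5,5,5,1,1,1,1,1,1,1,1
anthocyanin,x,x,x,x,x,x,x,x,x,1,1,1,1,1,1,1,1
beta-carotene hydroxylase,x,x,4,4,4,4,4,2,2,2,1,1,1,1,1,1,1
bHLH,x,x,x,x,x,x,x,x,x,1,1,1,1,1,1,1,1
carotenoid,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1
chlorophyll,x,x,x,x,x,3,3,3,1,1,1,1,1,1,1,1,1
ethylene,x,x,x,x,x,5,5,5,5,3,1,1,1,1,1,1,1
flavonoid,x,x,x,1,1,1,1,1,1,1,1,1,1,1,1,1,1
flavonol,x,x,x,x,x,x,x,x,x,x,x,x,x,x,1,1,1
hydroxycinnamic acid,x,x,x,x,x,x,x,x,1,1,1,1,1,1,1,1,1
lycopene,3,2,2,2,2,2,2,2,2,2,1,1,1,1,1,1,1
lycopene e-cyclase,x,x,x,x,x,x,2,2,2,2,1,1,1,1,1,1,1
phenolic,x,x,x,x,3,3,2,2,2,2,2,2,2,2,2,2,1
phenylalanine ammonia lyase,x,x,x,x,x,x,x,x,x,x,x,x,3,3,3,3,1
zeaxanthin epoxidase,x,x,3,3,3,3,3,2,2,2,1,1,1,1,1,1,1
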