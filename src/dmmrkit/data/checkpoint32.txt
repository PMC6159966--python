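CD28
ICOSLG
ICOS
TNFRSF9
TNFSF9
TNFSF4
TNFRSF4
CD70
CD27
CTLA4
PDCD1
CD274
PDCD1LG2
CD47
HAVCR2
LGALS9
ADORA2A
CD200
CD200R1
CD276
VTCN1
TNFSF14
BTLA
TIGIT
CD8A
PRF1
IL10
CD80
GZMA
CD86
IFNG
LAG3
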