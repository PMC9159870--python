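group,group_n,subtype,count
BOT,64,Serous,38
BOT,64,Mucinous,22
BOT,64,Endometrioid,2
BOT,64,Seromucinous,1
BOT,64,Other,1
EOC,28,Serous,12
EOC,28,Mucinous,11
EOC,28,Primary peritoneal cancer,2
EOC,28,Clear cell,2
EOC,28,Brenner,1
MOGCT,32,Immature teratoma,14
MOGCT,32,Dysgerminoma,16
MOGCT,32,Strumal carcinoid,2
MSCT,4,Sertoli-Leydig tumor,2
MSCT,4,Granulosa cell tumor,2
SCC,2,Small cell carcinoma (hypercalcaemic type),2
Metastatic carcinoma,7,Krukenberg tumor,4
Metastatic carcinoma,7,Cervix mixed adenocarcinoma,2
Metastatic carcinoma,7,B-cell lymphoma,1
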