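code,name,genus,subgenus,group,origin,n_families,n_hosts,abundance_period1,abundance_period2
A,Drosophila busckii,Drosophila,Dorsilopha,busckii,E,6,13,1198,1647
B,Drosophila cardini,Drosophila,Drosophila,cardini,N,9,14,121,412
C,Drosophila cardinoides,Drosophila,Drosophila,cardini,N,1,2,0,11
D,Drosophila immigrans,Drosophila,Drosophila,immigrans,E,4,4,8,140
E,Drosophila nasuta,Drosophila,Drosophila,immigrans,E,1,1,0,211
F,Drosophila hydei,Drosophila,Drosophila,repleta,E,11,14,14361,1049
G,Drosophila mercatorum,Drosophila,Drosophila,repleta,N,9,13,299,472
H,Drosophila repleta,Drosophila,Drosophila,repleta,N,1,1,0,17
I,Drosophila nebulosa,Drosophila,Drosophila,willistoni,N,4,4,25,0
J,Drosophila ananassae,Drosophila,Sophophora,melanogaster,E,10,14,424,2775
K,Drosophila kikkawai,Drosophila,Sophophora,melanogaster,E,1,1,2,0
L,Drosophila malerkotliana,Drosophila,Sophophora,melanogaster,E,6,6,592,0
M,Drosophila melanogaster,Drosophila,Sophophora,melanogaster,E,11,15,6838,3225
N,Drosophila simulans,Drosophila,Sophophora,melanogaster,E,15,22,7824,3739
O,Drosophila sturtevanti,Drosophila,Sophophora,saltans,N,1,1,0,85
P,Zaprionus indianus,Zaprionus,,,E,14,20,2154,1265
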