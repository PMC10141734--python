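code,scientific_name,family,origin,resource_type,popular_name,mass_g,empty_mass_pct,period1,period2
1,Actinidia chinensis,Actinidiaceae,E,FF,Kiwi,592.4,86.26,no_emergence,emerged
2,Beta vulgaris,Amaranthaceae,E,RT,Beetroot,482.9,100,absent,no_emergence
3,Allium cepa,Amaryllidaceae,E,SB,Onion,3037.1,57.81,emerged,emerged
4,Anacardium occidentale,Anacardiaceae,N,FF,Cashew fruit,524.0,25.38,emerged,absent
5,Mangifera indica,Anacardiaceae,E,FF,Mango,8595.8,69.42,emerged,emerged
6,Spondias mombin,Anacardiaceae,N,FF,Java plum,107.2,100,absent,no_emergence
7,Spondias purpurea,Anacardiaceae,N,FF,Purple mombin,8.9,100,absent,no_emergence
8,Annona squamosa,Annonaceae,N,FF,Custard apple,398.6,100,absent,no_emergence
9,Arracacia xanthorrhiza,Apiaceae,N,RT,Peruvian parsnip,79.7,100,absent,no_emergence
10,Daucus carota,Apiaceae,E,RT,Carrot,501.8,100,absent,no_emergence
11,Colocasia esculenta,Araceae,E,ST,Taro,711,73.42,emerged,absent
12,Lactuca sativa,Asteraceae,E,VL,Lettuce,290,0,emerged,absent
13,Brassica oleracea var. acephala,Brassicaceae,E,VL,Collard greens,59.9,100,absent,no_emergence
14,Brassica oleracea var. capitata,Brassicaceae,E,VL,Cabbage,585,0,emerged,absent
15,Ananas comosus,Bromeliaceae,N,FF,Pineapple,27195.5,0,emerged,emerged
16,Selenicereus undatus,Cactaceae,N,FF,Dragon fruit,205.9,100,absent,no_emergence
17,Carica papaya,Caricaceae,N,FF,Papaya,6256.2,87.24,no_emergence,emerged
18,Caryocar brasiliense,Caryocaraceae,N,FF,Pequi,171,17.54,emerged,absent
19,Ipomoea batatas,Convolvulaceae,N,RT,Sweet potato,125.2,100,absent,no_emergence
20,Cucumis anguria,Cucurbitaceae,E,FF,West indian gherkin,577.7,78.38,emerged,emerged
21,Citrullus lanatus,Cucurbitaceae,E,FF,Watermelon,6071.9,2.86,emerged,emerged
22,Cucumis melo,Cucurbitaceae,E,FF,Melon,962.9,0,emerged,emerged
23,Curcubita moschata,Cucurbitaceae,N,FF,Pumpkin,1497.3,11.98,emerged,emerged
24,Cucumis sativus,Cucurbitaceae,E,FF,Cucumber,844.7,58.01,emerged,emerged
25,Sicyos edulis,Cucurbitaceae,N,FF,Chayote,558.9,31.10,absent,emerged
26,Diospyros kaki,Ebenaceae,E,FF,Persimmon,282.8,100,absent,no_emergence
27,Persea americana,Lauraceae,N,FF,Avocado,1201.4,100,absent,no_emergence
28,Hibiscus esculentus,Malvaceae,N,DF,Okra,62.9,100,absent,no_emergence
29,Artocarpus heterophyllus,Moraceae,E,FF,Jackfruit,1490,0,emerged,absent
30,Musa x paradisiaca,Musaceae,E,FF,Banana,5860.3,34.55,emerged,emerged
31,Psidium guajava,Myrtaceae,N,FF,Guava,1035.7,54.28,no_emergence,emerged
32,Averrhoa carambola,Oxalidaceae,E,FF,Star fruit,105.3,13.58,emerged,no_emergence
33,Passiflora edulis,Passifloraceae,N,FF,Passion fruit,1800.9,43.17,emerged,emerged
34,Fragaria vesca,Rosaceae,N,FF,Strawberry,209.8,64.59,emerged,emerged
35,Malus domestica,Rosaceae,E,FF,Apple,5128,94.44,emerged,no_emergence
36,Prunus domestica,Rosaceae,E,FF,Plum,1393,63.03,emerged,emerged
37,Prunus persica,Rosaceae,E,FF,Peach,709,56.56,emerged,no_emergence
38,Prunus persica var. nucipersica,Rosaceae,E,FF,Nectarine,433.8,76.26,emerged,no_emergence
39,Pyrus communis,Rosaceae,E,FF,Pear,1568.4,73.64,emerged,emerged
40,Citrus x aurantiifolia,Rutaceae,E,FF,Lime,571,80.14,absent,emerged
41,Citrus x reticulata,Rutaceae,E,FF,Tangerine,2391,38.62,emerged,emerged
42,Citrus sinensis,Rutaceae,E,FF,Orange,2681.2,47.78,emerged,emerged
43,Litchi chinensis,Sapindaceae,E,FF,Lychee,19.9,100,absent,no_emergence
44,Capsicum annuum,Solanaceae,N,FF,Bell pepper,2346.5,71.02,emerged,emerged
45,Capsicum chinense,Solanaceae,N,FF,Chili pepper,25.5,100,absent,no_emergence
46,Solanum aethiopicum,Solanaceae,E,FF,Bitterberry,239.6,100,absent,no_emergence
47,Solanum lycopersicum,Solanaceae,N,FF,Tomato,5592,39.33,emerged,emerged
48,Solanum melongena,Solanaceae,E,FF,Eggplant,360.5,39.92,absent,emerged
49,Solanum tuberosum,Solanaceae,N,ST,Potato,3420.4,79.69,emerged,emerged
50,Vitis vinifera x Vitis labrusca,Vitaceae,EN,FF,Grape,108.4,40.96,emerged,no_emergence
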