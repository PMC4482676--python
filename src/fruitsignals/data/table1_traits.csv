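species,family,order,voc,uv_reflectance,blue_reflectance,green_reflectance,red_reflectance,lambda_max,peak_brightness,area_to_weight,n_fruits
Androstachys spp,Euphorbiaceae,Malpighiales,1.16,4.14,24.12,37.66,38.21,655,0.32,318.48,10
Antidesma petiolare,Euphorbiaceae,Malpighiales,34.34,1.99,13.01,46.27,40.72,700,0.34,849.49,5
Asterotrichilia asterotricha,Meliaceae,Sapindales,1.92,12.39,17.99,51.87,30.15,557,0.18,229.67,5
Asterotrichilia spp,Meliaceae,Sapindales,3.97,18.81,18.05,57.11,24.83,565,0.23,173.84,5
Asterotrichilia marina,Meliaceae,Sapindales,1.78,29.71,25.09,47.06,27.85,553,0.33,279.42,5
Badouinia fluggeiformis,Fabaceae,Fabales,5.22,8.7,11.63,59.83,28.54,700,0.4,373.06,5
Baudouinia spp,Fabaceae,Fabales,5.26,8.7,11.63,59.83,28.54,655,0.33,548.61,5
Berchemia discolor,Rhamnaceae,Rosales,4.51,0.19,0,95.86,4.14,562,0.24,350.79,5
Bridellia pervilleana,Euphorbiaceae,Malpighiales,5.86,2.75,1.95,59.98,38.07,691,0.09,662.4,10
Croton spp,Euphorbiaceae,Malpighiales,7.58,11.76,6.34,62.38,31.27,668,0.06,1291.5,10
Croton spp 2,Euphorbiaceae,Malpighiales,4.98,7.59,11.85,35.71,52.44,684,0.43,1340.7,10
Elaeocarpus subserratus,Elaeocarpaceae,Malvales,38.8,20.1,18.36,48.64,33,698,0.41,532.14,5
Empogona ovalifolia,Rubiaceae,Gentianales,10.3,15.58,11.02,60.39,28.59,700,0.21,720.51,5
Gaertnera spp,Rubiaceae,Gentianales,2.75,3.98,2.13,64.58,33.28,561,0.12,630.8,10
Garcinia arenicola,Clusiaceae,Malpighiales,1.28,7.89,8.37,56.41,35.23,698,0.12,255,5
Gardenia rutenbergiana,Rubiaceae,Gentianales,5.34,10.52,11.11,59.58,29.31,700,0.18,181.83,5
Grangeria spp,Chyrsobalanaceae,Rosales,9,3.79,9.41,45.44,45.15,699,0.34,429.01,5
Grewia madagascariensis,Malvaceae,Malvales,13.74,1.66,8.98,37.81,53.2,700,0.62,490.3,5
Grewia triflora,Malvaceae,Malvales,24.18,7.55,7.42,50.27,42.32,564,0.14,638.07,10
Landolphia myrtifolia,Apocynaceae,Gentianales,0.22,5.4,10.6,60.31,29.09,700,0.34,113.22,5
Mapouria boinensis,Rubiaceae,Gentianales,10.95,7.62,5.35,47.46,47.2,699,0.32,478.6,8
Mapouria spp,Rubiaceae,Gentianales,15.86,5.96,7.63,54.72,37.65,700,0.51,469.4,10
Monanthotaxis valida,Annonaceae,Magnoliales,10.93,5.5,9.08,56.44,34.48,700,0.6,410.89,5
Noronhia spp,Oleaceae,Lamiales,38.91,6.51,12.96,57.33,29.72,700,0.36,466.56,5
Petchia spp,Apocynaceae,Gentianales,1.79,20.67,26.28,35.2,38.52,669,0.84,1964.4,5
Rothmania renniformis,Rubiaceae,Gentianales,2.56,15.49,13.02,57.05,29.93,646,0.11,242.75,5
Rourea orientalis,Connaraceae,Rosales,4.22,15.46,17.66,52.64,29.7,692,0.49,506.1,5
Salvadora augustifolia,Salvadoraceae,Brassicales,1.98,13.44,15.15,44.4,40.44,563,0.31,758.21,5
Sorindeia madagascariensis,Anacardiaceae,Sapindales,1.39,11.59,19.83,37.5,42.67,631,0.21,244.17,6
Strychnos decussata,Loganiaceae,Gentianales,3.08,8.55,11.62,56.03,32.35,700,0.44,247.57,5
Strychnos madagascariensis,Loganiaceae,Gentianales,3.84,7.25,9.85,64.61,25.54,700,0.46,153.01,6
Strychnos spp.,Loganiaceae,Gentianales,4.21,2.66,6.04,65.22,28.75,697,0.62,240.62,5
Strychnos myrtoides,Loganiaceae,Gentianales,4.16,7.09,13.82,57.22,28.96,661,0.19,493.08,5
Strychnos spinosa,Loganiaceae,Gentianales,0.25,4.93,10.59,46.77,42.65,699,0.48,66.61,5
Tabernaemontana coffeeoides,Apocynaceae,Gentianales,2.52,5.43,27.41,35.49,37.1,571,0.43,325.88,5
Terminalia trophophylla,Combretaceae,Myrtales,23.3,7.44,8.65,59.68,31.67,551,0.17,1047.7,5
Tina isaloensis,Sapindaceae,Sapindales,2.26,58.39,32.85,28.59,38.56,692,0.3,1200.6,5
Tricalysia perrieri,Rubiaceae,Gentianales,15.75,12.92,13.03,59,27.96,697,0.21,614.93,10
UK Species 1,UK,UK,4.59,14.74,15.7,56.12,28.19,678,0.1,547.35,10
UK Species 2,UK,UK,13.95,16.85,13.47,51.04,35.49,638,0.21,157.38,5
UK Species 3,UK,UK,6.45,31.96,24.97,34.21,40.82,679,0.5,470.76,5
UK Species 4,UK,UK,0.5,12.02,11.76,58.25,29.99,697,0.39,123.83,5
UK Species 5,UK,UK,9.73,5.96,1.11,66.82,32.08,568,0.29,884.36,10
UK Species 6,UK,UK,23.25,23.04,4.85,71.76,23.39,567,0.17,674.54,10
UK Species 7,UK,UK,5.76,18.87,15.16,51.35,33.49,679,0.51,567.53,5
UK Species 8,UK,UK,45.91,3.42,8.11,59.15,32.75,580,0.19,428.23,5
UK Liana 1,UK,UK,9.35,2.9,3.93,56.83,39.24,578,0.12,530.81,5
UK Liana 2,UK,UK,1.94,5.19,4.47,58.64,36.89,562,0.24,316.26,5
UK Liana 3,UK,UK,2.81,15.61,26.17,38.72,35.11,699,0.18,582.08,10
UK Liana 4,UK,UK,17.14,22.94,4.03,45.37,50.6,700,0.21,447.56,6
UK Liana 5,UK,UK,53.44,12.79,3.44,65.51,31.05,646,0.27,513.3,5
Vitex beraviensis,Lamiaceae,Lamiales,1.08,11.78,11.81,57.02,31.17,684,0.1,106.74,5
Vitex perrieri,Lamiaceae,Lamiales,4.83,6.5,13.98,45.2,40.83,646,0.27,436.45,5
Vitex spp,Lamiaceae,Lamiales,1.28,3.89,9.06,54.64,36.3,630,0.13,311.88,5
Vitex spp 1,Lamiaceae,Lamiales,4.56,6.5,13.98,45.2,40.83,693,0.1,426.36,5
Ximenia caffra,Oleaceae,Lamiales,1.54,5.4,14.54,47.23,38.23,699,0.08,491.01,5
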