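specimen_id,taxon,endocast_cm3,brain_g,body_g,eq,group
Elephas_maximus_1,Elephas maximus,4550,4181,2267430,"1,83",proboscidean
Elephas_maximus_2,Elephas maximus,5220,4798,3216000,"1,62",proboscidean
Elephas_maximus_3,Elephas maximus,5000,4595,3450400,"1,48",proboscidean
Elephas_maximus_4,Elephas maximus,6075,5584,3190098,"1,90",proboscidean
Loxodonta_africana_1,Loxodonta africana,5712,5250,6654000,"1,05",proboscidean
Loxodonta_africana_2,Loxodonta africana,9000,8274,4380000,"2,23",proboscidean
Loxodonta_africana_3,Loxodonta africana,4000,3676,5174400,"0,88",proboscidean
Loxodonta_africana_4,Loxodonta africana,4050,3722,1793300,"1,93",proboscidean
Loxodonta_africana_5,Loxodonta africana,4420,4062,3505000,"1,29",proboscidean
Loxodonta_africana_6,Loxodonta africana,5300,4871,5550000,"1,11",proboscidean
Loxodonta_africana_7,Loxodonta africana,4480,4117,2750000,"1,56",proboscidean
Loxodonta_africana_8,Loxodonta africana,4210,3869,4000000,"1,12",proboscidean
Loxodonta_africana_9,Loxodonta africana,4100,3768,2160000,"1,70",proboscidean
Loxodonta_africana_10,Loxodonta africana,4000,3676,2537000,"1,48",proboscidean
Palaeoloxodon_falconeri_1,Palaeoloxodon falconeri,1800,1652,168000,"4,81",proboscidean
Palaeoloxodon_antiquus_1,Palaeoloxodon antiquus,5446,5005,3649880,"1,54",proboscidean
Palaeoloxodon_antiquus_2,Palaeoloxodon antiquus,9000,8274,11000000,"1,14",proboscidean
Mammuthus_primigenius_1,Mammuthus primigenius,4687,4307,6000000,"0,92",proboscidean
Mammuthus_meridionalis_1,Mammuthus meridionalis,5828,5357,11000000,"0,74",proboscidean
Mammuthus_columbi_1,Mammuthus columbi,6232,5728,9800000,"0,86",proboscidean
Mammut_americanum_1,Mammut americanum,3862,3549,6384056,"0,73",proboscidean
Mammut_americanum_2,Mammut americanum,4630,4255,8000000,"0,74",proboscidean
Stegodon_insignis_1,Stegodon insignis,3838,3527,2000000,"1,69",proboscidean
Zygolophodon_borsoni_1,Zygolophodon borsoni,5133,4718,16000000,"0,50",proboscidean
Palaeomastodon_beadnelli_1,Palaeomastodon beadnelli,771,706,2500000,"0,29",proboscidean
Moeritherium_lyonsi_1,Moeritherium lyonsi,240,218,810000,"0,20",proboscidean
Prorastomus_sirenoides_1,Prorastomus sirenoides,87,90,98156,"0,39",outgroup
Seggeurius_amourensis_1,Seggeurius amourensis,5,5,2932,"0,29",outgroup
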