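code,name,genus,family,guild,rank,total_root_mass_g,root_mass_rank,stem_abundance_rank,basal_area_rank
alsebl,Alseis blackiana,Alseis,Rubiaceae,tree,species,0.364,3,8,11
arec1,Arecaceae sp. 1,,Arecaceae,unknown,family,0.040,14,,
beilpe,Beilschmiedia pendula,Beilschmiedia,Lauraceae,tree,species,1.103,2,22,4
bign1,Bignoniaceae sp. 1,,Bignoniaceae,unknown,family,0.065,10,,
bign2,Bignoniaceae sp. 2,,Bignoniaceae,unknown,family,0.001,28,,
bign3,Bignoniaceae sp. 3,,Bignoniaceae,unknown,family,0.003,25,,
brosal,Brosimum alicastrum,Brosimum,Moraceae,tree,species,0.040,13,50,3
burs1,Burseraceae sp. 1,,Burseraceae,unknown,family,0.005,24,,
cela1,Celastraceae sp. 1,,Celastraceae,unknown,family,0.013,19,,
chry1,Chrysophyllum sp. 1,Chrysophyllum,Sapotaceae,unknown,genus,0.062,12,,
chry2,Chrysophyllum sp. 2,Chrysophyllum,Sapotaceae,unknown,genus,0.118,6,,
cocc1,Coccoloba sp. 1,Coccoloba,Polygonaceae,unknown,genus,0.001,28,,
couscu,Coussarea curvigemmia,Coussarea,Rubiaceae,tree,species,0.219,5,19,65
faba1,Fabaceae sp. 1,,Fabaceae,unknown,family,0.001,28,,
faraoc,Faramea occidentalis,Faramea,Rubiaceae,tree,species,0.010,20,1,5
guapst,Guapira standleyana,Guapira,Nyctaginaceae,tree,species,0.002,27,63,13
gustsu,Gustavia superba,Gustavia,Lecythidaceae,tree,species,0.108,7,95,61
hybapr,Hybanthus prunifolius,Hybanthus,Violaceae,tree,species,0.017,18,2,28
jacaco,Jacaranda copaia,Jacaranda,Bignoniaceae,tree,species,0.001,28,95,24
malp1,Malpighiaceae sp. 1,,Malpighiaceae,unknown,family,0.100,8,,
poutre,Pouteria reticulata,Pouteria,Sapotaceae,tree,species,0.006,22,50,22
prottn,Protium tenuifolium,Protium,Burseraceae,tree,species,0.001,32,20,19
quaras,Quararibea asterolepis,Quararibea,Malvaceae,tree,species,1.551,1,25,10
sapi1,Sapindaceae sp. 1,,Sapindaceae,unknown,family,0.029,16,,
tabegu,Tabebuia guayacan,Tabebuia,Bignoniaceae,tree,species,0.020,17,95,21
tabear,Tabernaemontana arborea,Tabernaemontana,Apocynaceae,tree,species,0.063,11,26,7
tachve,Tachigali versicolor,Tachigali,Fabaceae,tree,species,0.009,21,34,27
tetrpa,Tetragastris panamensis,Tetragastris,Burseraceae,tree,species,0.005,23,6,8
tricgi,Trichanthera gigantea,Trichanthera,Acanthaceae,tree,species,0.029,15,130,99
trictu,Trichilia tuberculata,Trichilia,Meliaceae,tree,species,0.253,4,7,2
ulma1,Ulmaceae sp. 1,,Ulmaceae,unknown,family,0.003,26,,
virose,Virola sebifera,Virola,Myristicaceae,tree,species,0.078,9,32,16
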