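biome,vertex_index,mat_c,precip_cm
tundra,0,-15,0
tundra,1,-5,0
tundra,2,-5,200
tundra,3,-15,200
boreal forest,0,-5,25
boreal forest,1,5,25
boreal forest,2,5,250
boreal forest,3,-5,250
temperate grassland/desert,0,-5,0
temperate grassland/desert,1,20,0
temperate grassland/desert,2,20,25
temperate grassland/desert,3,-5,25
woodland/shrubland,0,5,25
woodland/shrubland,1,20,25
woodland/shrubland,2,20,60
woodland/shrubland,3,5,60
temperate seasonal forest,0,5,60
temperate seasonal forest,1,20,60
temperate seasonal forest,2,20,225
temperate seasonal forest,3,5,225
temperate rain forest,0,5,225
temperate rain forest,1,20,225
temperate rain forest,2,20,450
temperate rain forest,3,5,450
subtropical desert,0,20,0
subtropical desert,1,30,0
subtropical desert,2,30,60
subtropical desert,3,20,60
tropical seasonal forest/savanna,0,20,60
tropical seasonal forest/savanna,1,30,60
tropical seasonal forest/savanna,2,30,250
tropical seasonal forest/savanna,3,20,250
tropical rain forest,0,20,250
tropical rain forest,1,30,250
tropical rain forest,2,30,450
tropical rain forest,3,20,450
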