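name,n_measured,mean_length_mm,sd_length_mm,mean_mass_mg,sd_mass_mg,microhabitat,initial_count_per_vessel
Asellus aquaticus adult,10,7.21,0.99,1.69,0.38,benthic,10
Chironomus sp. larva,10,9.12,0.71,0.31,0.069,benthic,10
Cloeon dipterum larva,10,6.87,0.89,1.02,0.21,benthic,10
Culex sp. larva,10,8.92,0.41,0.62,0.17,pelagic,10
Daphnia sp. adult,20,2.21,0.19,0.041,0.029,pelagic,30
Lymnaea stagnalis juvenile,10,9.65,0.77,7.84,2.01,pelagic,6
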