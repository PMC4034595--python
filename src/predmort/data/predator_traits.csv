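name,n_replicates,mean_length_mm,sd_length_mm,mass_mg,sd_mass_mg,foraging_mode,feeding_mode,microhabitat
Acilius canaliculatus adult,4,15.6,0.57,61.74,9.34,searching,chewing,benthic
Acilius canaliculatus L2,4,11.8,0.63,2.74,0.66,ambush,suctorial,pelagic
Acilius canaliculatus L3,4,22.2,1.75,14.66,4.70,ambush,suctorial,pelagic
Dytiscus marginalis adult,4,31.7,0.89,528.43,50.88,searching,chewing,benthic
Dytiscus marginalis L3,4,49.1,3.01,176.43,76.12,ambush,suctorial,pelagic
Hydaticus seminiger adult,4,14.5,0.32,64.94,8.42,searching,chewing,benthic
Ilyocoris cimicoides adult,4,13.9,0.60,34.43,6.85,searching,suctorial,benthic
Notonecta glauca adult,5,15.3,0.44,39.43,8.08,ambush,suctorial,pelagic
Anax imperator F-0,4,47.6,2.61,267.0,54.42,ambush,chewing,pelagic
Coenagrion puella F-0,4,12.8,0.87,4.80,0.99,ambush,chewing,pelagic
Libellula depressa F-0,5,22.3,1.11,58.41,19.51,ambush,chewing,benthic
Libellula depressa F-2,4,15.7,0.72,20.94,5.57,ambush,chewing,benthic
Sympetrum sanguineum F-0,4,16.1,0.97,20.82,4.49,ambush,chewing,pelagic
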