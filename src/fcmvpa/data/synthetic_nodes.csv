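name,x,y,z,space
Parahippocampal_Gyrus_R,24,-25,-12,MNI
Parahippocampal_Gyrus/Hippocampus_L,-24,-19,-15,MNI
Postcentral_Gyrus_L,-42,-25,42,MNI
Precentral_Gyrus_R,39,-13,42,MNI
Angular_Gyrus_L,-45,-64,33,MNI
Precuneus_L,-9,-61,39,MNI
Medial_Frontal_Gyrus/Anterior_Cingulate_L,-6,44,9,MNI
Middle_Temporal_Gyrus_R_#1,51,-34,-3,MNI
Middle_Temporal_Gyrus_R_#2,57,-52,3,MNI
Cerebellum_R,27,-64,-27,MNI
Inferior_Temporal_Gyrus_L,-51,-49,-15,MNI
Inferior_Parietal_Lobule_L,-39,-49,42,MNI
Fusiform_Gyrus_L,-39,-43,-18,MNI
Superior_Temporal_Gyrus_L,-54,-37,9,MNI
Parahippocampal_Gyrus_L,-21,-34,-9,MNI
Inferior_Frontal_Gyrus_R,48,20,12,MNI
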