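label,x,y,z
Right Superior Frontal Gyrus,20,30,48
Left Superior Frontal Gyrus,-20,30,48
Right Middle Frontal Gyrus,35,35,30
Left Middle Frontal Gyrus,-35,35,30
Right Inferior Frontal Gyrus,48,20,10
Left Inferior Frontal Gyrus,-48,20,10
Right Medial Frontal Gyrus,8,45,25
Left Medial Frontal Gyrus,-8,45,25
Right Orbital Gyrus,20,40,-15
Left Orbital Gyrus,-20,40,-15
Right Rectal Gyrus,6,30,-20
Left Rectal Gyrus,-6,30,-20
Right Precentral Gyrus,40,-12,45
Left Precentral Gyrus,-40,-12,45
Right Postcentral Gyrus,42,-25,48
Left Postcentral Gyrus,-42,-25,48
Right Paracentral Lobule,8,-30,55
Left Paracentral Lobule,-8,-30,55
Right Superior Parietal Lobule,28,-55,55
Left Superior Parietal Lobule,-28,-55,55
Right Inferior Parietal Lobule,45,-45,42
Left Inferior Parietal Lobule,-45,-45,42
Right Supramarginal Gyrus,52,-42,32
Left Supramarginal Gyrus,-52,-42,32
Right Angular Gyrus,45,-62,32
Left Angular Gyrus,-45,-62,32
Right Precuneus,10,-62,42
Left Precuneus,-10,-62,42
Right Superior Temporal Gyrus,55,-20,5
Left Superior Temporal Gyrus,-55,-20,5
Right Middle Temporal Gyrus,55,-35,-5
Left Middle Temporal Gyrus,-55,-35,-5
Right Inferior Temporal Gyrus,52,-30,-20
Left Inferior Temporal Gyrus,-52,-30,-20
Right Fusiform Gyrus,40,-45,-15
Left Fusiform Gyrus,-40,-45,-15
Right Parahippocampal Gyrus,26,-28,-12
Left Parahippocampal Gyrus,-26,-28,-12
Right Hippocampus,30,-25,-8
Left Hippocampus,-30,-25,-8
Right Amygdala,24,-4,-15
Left Amygdala,-24,-4,-15
Right Superior Occipital Gyrus,28,-80,28
Left Superior Occipital Gyrus,-28,-80,28
Right Middle Occipital Gyrus,32,-82,8
Left Middle Occipital Gyrus,-32,-82,8
Right Inferior Occipital Gyrus,32,-85,-8
Left Inferior Occipital Gyrus,-32,-85,-8
Right Cuneus,10,-80,25
Left Cuneus,-10,-80,25
Right Lingual Gyrus,14,-75,-5
Left Lingual Gyrus,-14,-75,-5
Right Insula,38,0,5
Left Insula,-38,0,5
Right Anterior Cingulate,6,35,12
Left Anterior Cingulate,-6,35,12
Right Mid Cingulate,6,-5,38
Left Mid Cingulate,-6,-5,38
Right Posterior Cingulate,6,-45,25
Left Posterior Cingulate,-6,-45,25
Right Caudate,12,10,10
Left Caudate,-12,10,10
Right Putamen,24,2,2
Left Putamen,-24,2,2
Right Globus Pallidus,18,-2,-2
Left Globus Pallidus,-18,-2,-2
Right Thalamus,12,-20,8
Left Thalamus,-12,-20,8
Cerebellar Vermis,0,-62,-28
Right Cerebellar Hemisphere,25,-60,-30
Left Cerebellar Hemisphere,-25,-60,-30
Brainstem,0,-25,-30
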