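feature_name,sequence,ccc,dr,icc_intra,icc_inter
shape_Maximum3DDiameter,T2w TSE,1.00,0.98,1.00,0.99
shape_MajorAxisLength,T2w TSE,0.99,0.98,0.99,1.00
shape_Elongation,T2w TSE,0.96,0.95,1.00,1.00
shape_Maximum2DDiameterSlice,T2w TSE,1.00,0.99,1.00,1.00
shape_MinorAxisLength,T2w TSE,0.99,0.96,0.99,1.00
shape_Maximum2DDiameterColumn,T2w TSE,1.00,0.98,1.00,0.99
shape_Maximum2DDiameterRow,T2w TSE,1.00,0.98,1.00,0.99
glcm_Imc1,T2w TSE,0.99,0.97,1.00,0.99
shape_Maximum3DDiameter,T1w TSE,1.00,0.97,1.00,0.99
shape_MajorAxisLength,T1w TSE,0.98,0.95,1.00,0.99
shape_Elongation,T1w TSE,0.99,0.95,1.00,0.99
shape_Maximum2DDiameterSlice,T1w TSE,1.00,0.98,1.00,1.00
shape_MinorAxisLength,T1w TSE,0.98,0.96,1.00,0.99
shape_Maximum2DDiameterColumn,T1w TSE,1.00,0.97,1.00,0.98
shape_Maximum2DDiameterRow,T1w TSE,0.99,0.97,1.00,0.98
glcm_Imc1,T1w TSE,0.93,0.91,1.00,0.97
shape_Maximum3DDiameter,FLAIR,1.00,0.97,1.00,0.98
shape_MajorAxisLength,FLAIR,1.00,0.96,0.99,0.98
shape_Elongation,FLAIR,0.98,0.96,0.99,0.99
shape_Maximum2DDiameterSlice,FLAIR,1.00,0.99,1.00,1.00
shape_MinorAxisLength,FLAIR,0.99,0.96,0.99,0.98
shape_Maximum2DDiameterColumn,FLAIR,1.00,0.97,1.00,0.98
shape_Maximum2DDiameterRow,FLAIR,0.99,0.95,0.99,0.97
glcm_Imc1,FLAIR,0.97,0.94,0.99,0.96
shape_Maximum3DDiameter,T2 map,0.99,0.96,1.00,0.99
shape_MajorAxisLength,T2 map,1.00,0.98,1.00,1.00
shape_Elongation,T2 map,0.92,0.93,0.99,0.99
shape_Maximum2DDiameterSlice,T2 map,0.99,0.98,1.00,0.99
shape_MinorAxisLength,T2 map,0.99,0.97,1.00,1.00
shape_Maximum2DDiameterColumn,T2 map,0.99,0.96,0.99,0.99
shape_Maximum2DDiameterRow,T2 map,0.99,0.95,0.99,0.98
glcm_Imc1,T2 map,1.00,0.97,0.99,0.99
shape_Maximum3DDiameter,HASTE,1.00,0.98,1.00,0.99
shape_MajorAxisLength,HASTE,0.99,0.97,0.99,0.99
shape_Elongation,HASTE,0.93,0.93,0.99,0.99
shape_Maximum2DDiameterSlice,HASTE,1.00,0.99,1.00,1.00
shape_MinorAxisLength,HASTE,0.99,0.96,0.99,0.99
shape_Maximum2DDiameterColumn,HASTE,0.99,0.96,0.99,0.99
shape_Maximum2DDiameterRow,HASTE,0.99,0.97,0.99,0.99
glcm_Imc1,HASTE,0.98,0.96,0.99,0.99
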