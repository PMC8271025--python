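feature_name,sequence,ccc,dr,icc_intra,icc_inter
shape_Maximum3DDiameter,T2 map,0.99205286,0.96251665,0.99716664,0.9867156
shape_MajorAxisLength,T2 map,0.99793419,0.97981361,0.996171,0.99749429
shape_Elongation,T2 map,0.9169208,0.92685464,0.99414914,0.99282215
shape_Maximum2DDiameterSlice,T2 map,0.99383495,0.97822157,0.99761689,0.9936394
shape_SurfaceArea,T2 map,0.99756368,0.93373906,0.99185998,0.87503941
shape_MinorAxisLength,T2 map,0.99207422,0.96696735,0.99616827,0.99825783
shape_Maximum2DDiameterColumn,T2 map,0.98837119,0.95757463,0.99194508,0.98736261
shape_Maximum2DDiameterRow,T2 map,0.99209873,0.95395661,0.99386968,0.97679991
gldm_GrayLevelVariance,T2 map,0.99604933,0.97096707,0.99580458,0.98995297
gldm_HighGrayLevelEmphasis,T2 map,0.9987185,0.99001813,0.99867983,0.99895219
gldm_DependenceEntropy,T2 map,0.9768604,0.93069293,0.97918853,0.95287381
gldm_GrayLevelNonUniformity,T2 map,0.99672213,0.96844026,0.99404055,0.90588485
gldm_SmallDependenceEmphasis,T2 map,0.99618473,0.97684637,0.99941963,0.99714743
gldm_SmallDependenceHighGrayLevelEmphasis,T2 map,0.99785548,0.99026715,0.99849964,0.99848907
gldm_DependenceNonUniformityNormalized,T2 map,0.98991352,0.97110551,0.99933187,0.99372596
gldm_LargeDependenceEmphasis,T2 map,0.99604457,0.97768667,0.99663332,0.9956135
gldm_DependenceVariance,T2 map,0.98074193,0.95832053,0.99468459,0.99131544
gldm_LargeDependenceHighGrayLevelEmphasis,T2 map,0.91063923,0.95569232,0.99721749,0.9746251
glcm_JointAverage,T2 map,0.99868486,0.98745931,0.99801085,0.99716702
glcm_SumAverage,T2 map,0.99868486,0.98745931,0.99801085,0.99716702
glcm_JointEntropy,T2 map,0.99586316,0.9719637,0.99865882,0.99477919
glcm_ClusterShade,T2 map,0.9839736,0.96063188,0.99510842,0.99205699
glcm_MaximumProbability,T2 map,0.97316718,0.95034713,0.98318707,0.97765663
glcm_Idmn,T2 map,0.97708482,0.95808548,0.99843989,0.98992028
glcm_JointEnergy,T2 map,0.99472158,0.97035282,0.98991929,0.9924416
glcm_Contrast,T2 map,0.99878665,0.98414808,0.99899223,0.99747783
glcm_DifferenceEntropy,T2 map,0.99888168,0.98304573,0.99946222,0.99795149
glcm_InverseVariance,T2 map,0.99783829,0.98143622,0.99945029,0.99754584
glcm_DifferenceVariance,T2 map,0.99659893,0.97714962,0.99846232,0.99813253
glcm_Idn,T2 map,0.970345,0.9541169,0.99815628,0.98941716
glcm_Idm,T2 map,0.99727834,0.98155574,0.99927382,0.99750192
glcm_Correlation,T2 map,0.93000815,0.91942547,0.98138967,0.98861346
glcm_Autocorrelation,T2 map,0.99882875,0.99071159,0.99869595,0.999001
glcm_SumEntropy,T2 map,0.99415534,0.96610084,0.99671268,0.9937416
glcm_MCC,T2 map,0.93302938,0.91561808,0.92970785,0.94261298
glcm_SumSquares,T2 map,0.99716854,0.97213991,0.99724918,0.99249056
glcm_ClusterProminence,T2 map,0.98931893,0.96491762,0.99077845,0.98964681
glcm_Imc2,T2 map,0.97815659,0.92212229,0.97592009,0.9396985
glcm_Imc1,T2 map,0.99777137,0.97086093,0.99426633,0.99035433
glcm_DifferenceAverage,T2 map,0.99848775,0.98296153,0.99937115,0.99702514
glcm_Id,T2 map,0.99726682,0.98139837,0.99930241,0.99748562
glcm_ClusterTendency,T2 map,0.99642325,0.9699074,0.99671296,0.99142976
firstorder_InterquartileRange,T2 map,0.99521994,0.97486054,0.99841554,0.99669589
firstorder_Uniformity,T2 map,0.99336279,0.96426864,0.99280367,0.99113126
firstorder_Median,T2 map,0.99824873,0.9849003,0.9999125,0.99978288
firstorder_Energy,T2 map,0.99285535,0.95932458,0.99901088,0.92817079
firstorder_RobustMeanAbsoluteDeviation,T2 map,0.99779342,0.97649493,0.99844399,0.99691045
firstorder_MeanAbsoluteDeviation,T2 map,0.99844334,0.97694624,0.99821731,0.99604297
firstorder_TotalEnergy,T2 map,0.99285535,0.95932458,0.99901088,0.92817079
firstorder_RootMeanSquared,T2 map,0.99884074,0.98651296,0.99989506,0.9997983
firstorder_90Percentile,T2 map,0.99935775,0.99013933,0.99995552,0.99994976
firstorder_Minimum,T2 map,0.9698354,0.92185515,0.92678063,0.8563204
firstorder_Entropy,T2 map,0.99424781,0.96641727,0.99700328,0.99412676
firstorder_Variance,T2 map,0.99606424,0.97099704,0.99579973,0.98995292
firstorder_10Percentile,T2 map,0.99778937,0.97865487,0.99899933,0.99627425
firstorder_Kurtosis,T2 map,0.93847516,0.90984293,0.95408877,0.97436669
firstorder_Mean,T2 map,0.99880578,0.98622651,0.99989669,0.99974019
glrlm_GrayLevelVariance,T2 map,0.9958799,0.970434,0.99549048,0.98993049
glrlm_GrayLevelNonUniformityNormalized,T2 map,0.99543004,0.96647932,0.99413525,0.99112422
glrlm_RunVariance,T2 map,0.99473224,0.9734017,0.99380636,0.99548573
glrlm_GrayLevelNonUniformity,T2 map,0.99949804,0.9674928,0.99614749,0.90009412
glrlm_LongRunEmphasis,T2 map,0.99714509,0.97728321,0.99490007,0.99758722
glrlm_ShortRunHighGrayLevelEmphasis,T2 map,0.99887822,0.9896169,0.99863031,0.99910028
glrlm_ShortRunEmphasis,T2 map,0.99850478,0.9822178,0.99846149,0.99790335
glrlm_LongRunHighGrayLevelEmphasis,T2 map,0.99248684,0.9784732,0.99830025,0.99622993
glrlm_RunPercentage,T2 map,0.99663584,0.97947032,0.99853888,0.99734065
glrlm_RunEntropy,T2 map,0.99144107,0.95450254,0.99513693,0.98727089
glrlm_HighGrayLevelRunEmphasis,T2 map,0.99875561,0.98967427,0.99862958,0.99894877
glrlm_RunLengthNonUniformityNormalized,T2 map,0.99765911,0.98130563,0.99893779,0.99778324
glszm_GrayLevelVariance,T2 map,0.9664123,0.93487499,0.97426499,0.97948862
glszm_ZoneVariance,T2 map,0.99376813,0.97889386,0.98567831,0.91246949
glszm_GrayLevelNonUniformityNormalized,T2 map,0.97487458,0.93998164,0.99321227,0.98660887
glszm_SizeZoneNonUniformityNormalized,T2 map,0.96600087,0.93446205,0.99453147,0.97741752
glszm_SizeZoneNonUniformity,T2 map,0.97920816,0.92353173,0.99747104,0.77391648
glszm_LargeAreaEmphasis,T2 map,0.99376008,0.97890241,0.98569335,0.91286785
glszm_SmallAreaHighGrayLevelEmphasis,T2 map,0.99850607,0.98619218,0.9981323,0.99889261
glszm_ZonePercentage,T2 map,0.99601524,0.97623238,0.99938994,0.99740069
glszm_LargeAreaLowGrayLevelEmphasis,T2 map,0.95717008,0.96966115,0.94344936,0.94615198
glszm_HighGrayLevelZoneEmphasis,T2 map,0.99826972,0.98491803,0.99815622,0.99876604
glszm_SmallAreaEmphasis,T2 map,0.96165228,0.93147704,0.99401327,0.9749973
glszm_ZoneEntropy,T2 map,0.95503524,0.92776222,0.96164933,0.96298698
ngtdm_Complexity,T2 map,0.97512148,0.95607862,0.97876807,0.98862786
ngtdm_Contrast,T2 map,0.99332362,0.9725499,0.99853608,0.99306747
ngtdm_Busyness,T2 map,0.99582432,0.93702781,0.96571588,0.9623215
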