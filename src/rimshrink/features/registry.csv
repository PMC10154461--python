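name,class,family
firstorder_Energy,FF,firstorder
firstorder_TotalEnergy,FF,firstorder
firstorder_Entropy,FF,firstorder
firstorder_Minimum,FF,firstorder
firstorder_Percentile10,FF,firstorder
firstorder_Percentile90,FF,firstorder
firstorder_Maximum,FF,firstorder
firstorder_Mean,FF,firstorder
firstorder_Median,FF,firstorder
firstorder_InterquartileRange,FF,firstorder
firstorder_Range,FF,firstorder
firstorder_MeanAbsoluteDeviation,FF,firstorder
firstorder_RobustMeanAbsoluteDeviation,FF,firstorder
firstorder_RootMeanSquared,FF,firstorder
firstorder_Skewness,FF,firstorder
firstorder_Kurtosis,FF,firstorder
firstorder_Variance,FF,firstorder
firstorder_Uniformity,FF,firstorder
shape_MeshVolume,MF,shape
shape_VoxelVolume,MF,shape
shape_SurfaceArea,MF,shape
shape_SurfaceVolumeRatio,MF,shape
shape_Sphericity,MF,shape
shape_Maximum3DDiameter,MF,shape
shape_Maximum2DDiameterSlice,MF,shape
shape_Maximum2DDiameterColumn,MF,shape
shape_Maximum2DDiameterRow,MF,shape
shape_MajorAxisLength,MF,shape
shape_MinorAxisLength,MF,shape
shape_LeastAxisLength,MF,shape
shape_Elongation,MF,shape
shape_Flatness,MF,shape
glcm_Autocorrelation,TF,glcm
glcm_JointAverage,TF,glcm
glcm_ClusterProminence,TF,glcm
glcm_ClusterShade,TF,glcm
glcm_ClusterTendency,TF,glcm
glcm_Contrast,TF,glcm
glcm_Correlation,TF,glcm
glcm_DifferenceAverage,TF,glcm
glcm_DifferenceEntropy,TF,glcm
glcm_DifferenceVariance,TF,glcm
glcm_JointEnergy,TF,glcm
glcm_JointEntropy,TF,glcm
glcm_Imc1,TF,glcm
glcm_Imc2,TF,glcm
glcm_Idm,TF,glcm
glcm_Idmn,TF,glcm
glcm_Id,TF,glcm
glcm_Idn,TF,glcm
glcm_InverseVariance,TF,glcm
glcm_MaximumProbability,TF,glcm
glcm_SumEntropy,TF,glcm
glrlm_ShortRunEmphasis,TF,glrlm
glrlm_LongRunEmphasis,TF,glrlm
glrlm_GrayLevelNonUniformity,TF,glrlm
glrlm_GrayLevelNonUniformityNormalized,TF,glrlm
glrlm_RunLengthNonUniformity,TF,glrlm
glrlm_RunLengthNonUniformityNormalized,TF,glrlm
glrlm_RunPercentage,TF,glrlm
glrlm_GrayLevelVariance,TF,glrlm
glrlm_RunVariance,TF,glrlm
glrlm_RunEntropy,TF,glrlm
glrlm_LowGrayLevelRunEmphasis,TF,glrlm
glrlm_HighGrayLevelRunEmphasis,TF,glrlm
glrlm_ShortRunLowGrayLevelEmphasis,TF,glrlm
glrlm_ShortRunHighGrayLevelEmphasis,TF,glrlm
glrlm_LongRunLowGrayLevelEmphasis,TF,glrlm
glrlm_LongRunHighGrayLevelEmphasis,TF,glrlm
glszm_SmallAreaEmphasis,TF,glszm
glszm_LargeAreaEmphasis,TF,glszm
glszm_GrayLevelNonUniformity,TF,glszm
glszm_GrayLevelNonUniformityNormalized,TF,glszm
glszm_SizeZoneNonUniformity,TF,glszm
glszm_SizeZoneNonUniformityNormalized,TF,glszm
glszm_ZonePercentage,TF,glszm
glszm_GrayLevelVariance,TF,glszm
glszm_ZoneVariance,TF,glszm
glszm_ZoneEntropy,TF,glszm
glszm_LowGrayLevelZoneEmphasis,TF,glszm
glszm_HighGrayLevelZoneEmphasis,TF,glszm
glszm_SmallAreaLowGrayLevelEmphasis,TF,glszm
glszm_SmallAreaHighGrayLevelEmphasis,TF,glszm
glszm_LargeAreaLowGrayLevelEmphasis,TF,glszm
glszm_LargeAreaHighGrayLevelEmphasis,TF,glszm
gldm_SmallDependenceEmphasis,TF,gldm
gldm_LargeDependenceEmphasis,TF,gldm
gldm_GrayLevelNonUniformity,TF,gldm
gldm_DependenceNonUniformity,TF,gldm
gldm_DependenceNonUniformityNormalized,TF,gldm
gldm_GrayLevelVariance,TF,gldm
gldm_DependenceVariance,TF,gldm
gldm_DependenceEntropy,TF,gldm
gldm_LowGrayLevelEmphasis,TF,gldm
gldm_HighGrayLevelEmphasis,TF,gldm
gldm_SmallDependenceLowGrayLevelEmphasis,TF,gldm
gldm_SmallDependenceHighGrayLevelEmphasis,TF,gldm
gldm_LargeDependenceLowGrayLevelEmphasis,TF,gldm
gldm_LargeDependenceHighGrayLevelEmphasis,TF,gldm
ngtdm_Coarseness,TF,ngtdm
ngtdm_Contrast,TF,ngtdm
ngtdm_Complexity,TF,ngtdm
ngtdm_Busyness,TF,ngtdm
ngtdm_Strength,TF,ngtdm
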