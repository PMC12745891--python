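patient_id,organ,modality,dx_mm,dy_mm,dz_mm,euclidean_mm,derivable_euclidean
1,liver,AX_MR,4.1,9.2,7.0,12.3,True
2,liver,AX_MR,1.1,3.1,2.7,4.3,True
1,liver,COR_MR,7.7,9.0,9.7,15.3,True
2,liver,COR_MR,0.4,2.5,2.4,3.4,True
1,liver,CT,4.2,4.3,16.4,17.4,True
2,liver,CT,0.4,0.2,0.2,0.5,True
1,kidney_mean,AX_MR,1.0,1.8,7.6,8.0,False
2,kidney_mean,AX_MR,0.9,1.1,3.1,3.6,False
3,kidney_mean,AX_MR,1.6,2.2,6.3,7.0,False
1,kidney_mean,COR_MR,0.6,2.5,9.6,10.0,False
2,kidney_mean,COR_MR,1.5,0.3,2.4,2.8,False
3,kidney_mean,COR_MR,1.7,2.5,7.0,7.8,False
1,kidney_mean,CT,1.6,0.6,5.5,5.7,False
2,kidney_mean,CT,2.4,1.9,1.0,3.5,False
3,kidney_mean,CT,1.0,0.6,4.4,4.5,False
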