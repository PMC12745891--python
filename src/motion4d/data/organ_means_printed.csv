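organ,modality,dx,dy,dz,euclidean
liver,AX_MR,2.6,6.2,4.9,8.3
liver,COR_MR,4.1,5.7,6.0,9.4
liver,CT,2.3,2.2,8.3,9.0
kidney_mean,AX_MR,1.1,1.6,5.6,6.1
kidney_mean,COR_MR,1.2,1.7,6.3,6.8
kidney_mean,CT,1.7,1.0,3.6,4.6
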