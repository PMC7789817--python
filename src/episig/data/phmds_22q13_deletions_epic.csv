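sample_id,cohort,chrom,start,end,length_mb,signature
MS2676,small_del,chr22,51135138,51147735,0.013,False
MS2675,small_del,chr22,51135138,51147735,0.013,False
MS2450,small_del,chr22,51123475,51225561,0.1,False
MS2456,small_del,chr22,50580743,51225561,0.64,False
MS2454,small_del,chr22,50248907,51225561,0.98,False
MS2463,large_del,chr22,49238268,51225561,1.99,True
MS2444,large_del,chr22,48872890,51225561,2.35,True
MS2443,large_del,chr22,48651166,51214353,2.56,True
MS2441,large_del,chr22,48231823,51225561,2.99,True
MS2445,large_del,chr22,47557457,51225561,3.67,True
MS2447,large_del,chr22,46895349,51225561,4.33,True
MS2442,large_del,chr22,46507241,51214353,4.71,True
MS2440,large_del,chr22,46458783,51221675,4.76,True
MS2458,large_del,chr22,46084862,51225561,5.14,True
MS2465,large_del,chr22,45558433,51225561,5.67,True
MS2462,large_del,chr22,45250061,51225561,5.98,True
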