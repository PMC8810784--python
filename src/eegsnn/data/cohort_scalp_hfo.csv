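patient_id,surgery_index,phase,age,sex,etiology,seizure_freq,ilae,hfo_rate_affected,hfo_rate_nonaffected
1,1,pre,4,f,Sturge Weber syndrome,30,,6.38,6.88
2,1,pre,5,m,FCD 1a,180,,5.6,0.54
2,2,pre,7,m,FCD 1a,180,,1.93,1.26
3,1,pre,10,m,diffuse astrocytoma,0.5,,0.66,0.73
4,1,pre,3,m,mMCD,2,,0.24,1.1
5,1,pre,13,m,cavernoma,8,,0.88,0.07
6,1,pre,15,m,DNET,12,,0.11,0.22
7,1,pre,14,f,ganglioglioma,4,,0.85,0.15
8,1,pre,1,f,"polymicrogyria, FCD 1a",450,,8.78,2.39
1,1,post,4,f,Sturge Weber syndrome,0.2,3,0.13,0.01
2,1,post,5,m,FCD 1a,180,5,2.05,1.28
2,2,post,7,m,FCD 1a,0,1,0.09,0.09
3,1,post,10,m,diffuse astrocytoma,1,3,0.79,0.76
4,1,post,3,m,mMCD,150,5,4.1,5.09
5,1,post,13,m,cavernoma,0,1,0.02,0
6,1,post,15,m,DNET,0,1,0.03,0.01
7,1,post,14,f,ganglioglioma,0,1,0.05,0.13
9,1,post,3,m,FCD 2a,0,1,0.1,0.1
10,1,post,6,f,angiocentric glioma,0.3,5,0.11,0.07
11,1,post,17,m,perinatal ischemic lesion,0,1,0.17,0.53
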