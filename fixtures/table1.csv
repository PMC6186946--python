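id,group,age,sex,hemi,onset,duration,fc,viq,piq,blurring,surgery,hippocampal_histology,temporal_histology,engel,aeds
1,patient,12.09,F,R,0.5,11.59,y,81,86,Y,Y,ILAE Type I HS,FCD IIIA,Ia,"LVT, TPR"
2,patient,11.38,M,L,2,9.38,y,53,55,Y,N,,,,TPR
3,patient,13.75,F,L,4,9.75,n,108,125,N,Y,ILAE Type I HS,FCD IIIA,Ib,"CBZ, LVT"
4,patient,7.03,F,L,4.5,2.53,n,112,110,N,N,,,,"LVT, VPA, OXCBZ"
5,patient,11.72,F,R,1.5,10.22,n,83,90,N,N,,,,LVT
6,patient,11.95,M,R,7,4.95,n,n.a.,n.a.,Y,N,,,,None
7,patient,13.57,F,R,0.83,12.74,y,87,86,N,N,,,,"VPA, OXCBZ"
8,patient,12.01,F,R,1.5,10.51,y,65,84,N,N,,,,"CBZ, TPR"
9,patient,8.68,F,L,1.5,7.18,y,87,88,N,Y,ILAE Type I HS,Nonspecific changes,Ia,"LVT, VPA"
10,patient,13.92,F,R,0.92,13,y,108,100,Y,N,,,,VPA
11,patient,10.06,F,L,0.25,9.81,n,n.a.,n.a.,N,N,,,,"LVT, VPA"
12,patient,4.71,F,L,1,3.71,y,93,79,Y,Y,ILAE Type I HS,Nonspecific changes,IIIa,"LVT, CLB, OXCBZ"
13,patient,8.53,M,R,1.5,7.03,y,69,77,Y,Y,ILAE Type I HS,Nonspecific changes,Ia,"CBZ, LVT"
14,patient,8.01,F,L,1,7.01,y,99,94,Y,N,,,,"VPA, LVT"
15,patient,10.21,M,L,3.5,6.71,n,81,92,Y,Y,No diagnosis,Nonspecific changes,Ia,"TPR, LVT"
16,patient,14.87,M,L,9,5.87,n,105,109,N,Y,Gliosis only,Reactive cavities,IIa,"LTG, CLB, zonisamide, perampanel"
17,patient,15.09,F,L,0.75,14.34,n,108,117,N,N,,,,"OXCBZ, LVT"
18,patient,4.55,F,R,0.75,3.8,n,n.a.,n.a.,Y,Y,ILAE Type II HS,Mild atrophy,Ia,"VPA, LTG"
19,patient,6.95,M,L,0.33,6.62,n,45,49,Y,Y,ILAE Type I HS,Nonspecific changes,Ia,CBZ
20,patient,11.63,M,L,7,4.63,n,98,100,N,N,,,,"VPA, TPR, LTG"
21,patient,5.96,M,L,5,0.96,n,n.a.,n.a.,N,N,,,,Midazolam
22,patient,15.08,M,R,12,3.08,n,n.a.,n.a.,N,N,,,,"LTG, VPA"
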