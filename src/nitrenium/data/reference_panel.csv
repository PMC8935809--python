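no,cas,name,smiles,ames,ddE_ref,gt1_bmut,leadscope,derek,gt_expert
1,142-04-1,Aniline hydrochloride,Cl.Nc1ccccc1,nonmutagen,0.0,Inconclusive,Indeterminate,Inactive,Known Negative
2,95-53-4,o-Toluidine,Cc1ccccc1N,mutagen,-5.6,Positive,Indeterminate,Inactive,Known Positive
3,108-44-1,m-Toluidine,Cc1cccc(N)c1,nonmutagen,-1.7,Inconclusive,Indeterminate,Inactive,Known Negative
4,106-49-0,p-Toluidine,Cc1ccc(N)cc1,nonmutagen,-6.7,Positive,Active,Inactive,Known Negative
5,87-62-7,"2,6-Dimethylaniline",Cc1cccc(C)c1N,mutagen,-9.8,Negative,Indeterminate,Plausible,Known Positive
6,95-68-1,"2,4-Dimethylaniline",Cc1ccc(N)c(C)c1,mutagen,-11.6,Positive,Active,Plausible,Known Positive
7,95-78-3,"2,5-Dimethylaniline",Cc1ccc(C)c(N)c1,mutagen,-7.2,Positive,Indeterminate,Plausible,Known Positive
8,88-05-1,"2,4,6-Trimethylaniline",Cc1cc(C)c(N)c(C)c1,mutagen,-15.4,Inconclusive,Active,Plausible,Known Positive
9,134-29-2,o-Anisidine hydrochloride,Cl.COc1ccccc1N,mutagen,-15.4,Positive,Active,Plausible,Known Positive
10,536-90-3,m-Anisidine,COc1cccc(N)c1,mutagen,2.1,Positive,Inactive,Plausible,Known Positive
11,104-94-9,p-Anisidine,COc1ccc(N)cc1,mutagen,-16.7,Positive,Active,Plausible,Known Positive
12,88-21-1,2-Aminobenzenesulfonic acid,Nc1ccccc1S(=O)(=O)O,nonmutagen,19.6,Positive,Inactive,Inactive,Known Negative
13,121-47-1,3-Aminobenzenesulfonic acid,Nc1cccc(c1)S(=O)(=O)O,nonmutagen,10.7,Negative,Inactive,Inactive,Known Negative
14,121-57-3,Sulfanilic acid,Nc1ccc(cc1)S(=O)(=O)O,nonmutagen,24.1,Negative,Inactive,Inactive,Known Negative
15,98-18-0,3-Aminobenzenesulfonamide,Nc1cccc(c1)S(N)(=O)=O,nonmutagen,5.3,Negative,Inactive,Inactive,Negative
16,63-74-1,Sulfanilamide,Nc1ccc(cc1)S(N)(=O)=O,nonmutagen,15.5,Negative,Inactive,Inactive,Known Negative
17,98-33-9,4-Amino-3-methylbenzenesulfonic acid,Cc1cc(ccc1N)S(=O)(=O)O,nonmutagen,17.4,Positive,Inactive,Inactive,Known Negative
18,52727-57-8,Methyl 2-amino-5-bromobenzoate,COC(=O)c1cc(Br)ccc1N,nonmutagen,11.0,Negative,Inactive,Inactive,Known Negative
19,445-03-4,2-Amino-5-chlorobenzotrifluoride,Nc1ccc(Cl)cc1C(F)(F)F,nonmutagen,13.8,Negative,Inactive,Inactive,Known Negative
20,106-40-1,4-Bromoaniline,Nc1ccc(Br)cc1,nonmutagen,3.8,Positive,Inactive,Inactive,Known Negative
21,134-20-3,Methyl anthranilate,COC(=O)c1ccccc1N,nonmutagen,7.4,Negative,Inactive,Inactive,Known Negative
22,88-17-5,2-Aminobenzotrifluoride,Nc1ccccc1C(F)(F)F,nonmutagen,14.4,Negative,Inactive,Inactive,Known Negative
23,106-47-8,4-Chloroaniline,Nc1ccc(Cl)cc1,mutagen,0.4,Positive,Inactive,Inactive,Known Positive
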