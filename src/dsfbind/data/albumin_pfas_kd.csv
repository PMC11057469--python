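protein,ligand,chain_length,kd_mM,kd_sem_mM,dtm_max_C,dtm_max_sem_C,r2,n
HSA,PFBA,4,2.64,0.22,6.43,0.43,0.96,6
BSA,PFBA,4,3.06,0.27,10.5,0.18,0.93,12
PSA,PFBA,4,1.28,0.03,6.89,0.07,0.89,6
RSA,PFBA,4,1.90,0.09,7.06,0.09,0.92,6
HSA,PFHxA,6,1.71,0.22,10.5,0.14,0.98,
BSA,PFHxA,6,2.17,0.06,17.1,0.14,0.98,
PSA,PFHxA,6,0.95,0.02,13.9,0.14,0.97,
RSA,PFHxA,6,1.33,0.02,12.2,0.09,0.97,
HSA,PFOA,8,0.79,0.09,13.0,0.41,0.97,6
BSA,PFOA,8,0.99,0.01,14.4,0.19,0.92,6
PSA,PFOA,8,0.37,0.01,9.68,0.07,0.89,9
RSA,PFOA,8,0.40,0.01,8.0,0.13,0.97,6
HSA,PFBS,4,1.68,0.09,11.7,0.21,0.98,6
BSA,PFBS,4,0.80,0.03,15.3,0.12,0.99,6
PSA,PFBS,4,1.25,0.02,12.2,0.06,0.95,6
RSA,PFBS,4,1.41,0.03,10.1,0.08,0.96,6
HSA,PFOS,8,0.69,0.02,15.9,0.63,0.93,5
BSA,PFOS,8,0.86,0.05,15.3,0.23,0.79,9
PSA,PFOS,8,0.38,0.06,5.74,0.20,0.85,9
RSA,PFOS,8,0.42,0.10,4.76,0.38,0.87,9
HSA,HFPO-DA,5,1.57,0.03,13.7,0.09,0.95,
BSA,HFPO-DA,5,2.55,0.13,12.7,0.11,0.95,
PSA,HFPO-DA,5,2.12,0.03,10.0,0.15,0.93,
RSA,HFPO-DA,5,1.64,0.05,7.56,0.10,0.94,
HSA,6:2 FTOH,6,N/A,N/A,N/A,N/A,N/A,
BSA,6:2 FTOH,6,N/A,N/A,N/A,N/A,N/A,
PSA,6:2 FTOH,6,N/A,N/A,N/A,N/A,N/A,
RSA,6:2 FTOH,6,N/A,N/A,N/A,N/A,N/A,
HSA,6:2 FTSA,6,0.41,0.04,3.53,0.26,0.82,
BSA,6:2 FTSA,6,1.39,0.04,17.2,0.19,0.81,
PSA,6:2 FTSA,6,0.52,0.03,8.72,0.09,0.93,
RSA,6:2 FTSA,6,0.33,0.02,7.99,0.10,0.99,
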