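compound_id,smiles,pic50_alpha,pic50_beta,s
compound1,Oc1ccc(-c2cc(F)c3c(Cl)c(O)ccc3c2)cc1,6.40,7.96,1.55
compound2,C#Cc1cc(O)cc2ccc(-c3ccc(O)c(F)c3)cc12,6.14,7.92,1.78
compound3,Oc1cc(F)c2cc(-c3ccc(O)c(F)c3)ccc2c1,6.68,7.82,1.11
compound4,N#Cc1cc(O)cc2ccc(-c3ccc(O)cc3)cc12,6.08,7.70,1.61
compound5,N#Cc1cc(O)cc2ccc(-c3c(F)cc(O)cc3F)cc12,6.35,7.66,1.29
compound6,N#Cc1cc(-c2ccc(O)cc2)cc2ccc(O)cc12,5.98,7.64,1.65
compound7,CCc1cc(-c2ccc(O)c(F)c2)cc2ccc(O)cc12,5.95,7.60,1.65
compound8,N#Cc1cc(-c2ccc(O)c(F)c2)cc2ccc(O)cc12,5.68,7.57,1.89
compound9,Oc1ccc(-c2ccc3c(Cl)c(O)ccc3c2)c(Cl)c1,6.44,7.48,1.00
compound10,Oc1ccc2nc(-c3ccc(O)c(F)c3)cc(Br)c2c1,5.55,7.47,1.92
compound11,Oc1ccc(-c2cc(Br)c3cc(O)ccc3n2)cc1,5.67,7.37,1.68
compound12,Oc1ccc(-c2cc(Cl)c3cc(O)ccc3n2)cc1,5.67,7.34,1.66
compound13,Oc1ccc2nc(-c3ccc(O)c(F)c3)cc(Cl)c2c1,5.61,7.28,1.66
compound14,Cc1c(O)cc(C#N)c2cc(-c3ccc(O)c(F)c3)ccc12,5.39,7.22,1.82
compound15,Oc1ccc(-c2ccc3c(F)c(O)ccc3c2)cc1,6.11,7.15,1.00
compound16,Oc1ccc2cc(-c3cc(F)c(O)c(F)c3)ccc2c1,6.04,7.08,1.00
compound17,O=Cc1cc(O)cc2ccc(-c3ccc(O)c(F)c3)cc12,6.14,7.96,1.82
compound18,Oc1ccc(-c2ccc3cc(O)ccc3c2)c(Cl)c1,7.00,7.85,0.79
compound19,Oc1ccc(-c2cc(F)c3cc(O)ccc3c2)cc1,6.66,7.80,1.11
compound20,N#Cc1cc(O)cc2ccc(-c3ccc(O)c(F)c3)cc12,6.02,7.68,1.65
compound21,Oc1ccc(-c2cc(Cl)c3cc(O)ccc3c2)cc1,6.52,7.64,1.08
compound22,CCc1cc(-c2ccc(O)c(F)c2)cc2ccc(O)cc12,5.63,7.62,1.99
compound23,Oc1ccc(-c2ccc3c(Cl)c(O)ccc3c2)cc1,6.04,7.60,1.55
compound24,Oc1ccc2cc(-c3cc(F)c(O)cc3F)ccc2c1,6.57,7.55,0.94
compound25,Oc1cc(F)c(-c2ccc3c(Cl)c(O)ccc3c2)c(F)c1,6.46,7.47,0.97
compound26,Oc1ccc(-c2ccc3c(Cl)c(O)ccc3c2)cc1F,5.84,7.40,1.54
compound27,N#Cc1cc(O)c(Br)c2ccc(-c3ccc(O)c(F)c3)cc12,5.94,7.35,1.39
compound28,Oc1ccc2cc(-c3ccc(O)c(F)c3)ccc2c1,6.04,7.30,1.24
compound29,CC#Cc1cc(O)cc2ccc(-c3ccc(O)c(F)c3)cc12,5.74,7.26,1.50
compound30,N#Cc1cc(-c2cc(F)c(O)cc2F)cc2ccc(O)cc12,5.73,7.16,1.41
compound31,C=Cc1cc(O)cc2ccc(-c3ccc(O)c(F)c3)cc12,5.28,7.14,1.85
compound32,Oc1cc(F)c(-c2ccc3c(Cl)c(O)ccc3c2)cc1F,5.93,7.07,1.11
compound33,Cc1cc(O)ccc1-c1ccc2cc(O)ccc2c1,6.40,7.00,0.48
compound34,Oc1ccc2cc(-c3cc(F)c(O)c(F)c3)ccc2c1Cl,5.28,6.97,1.68
compound35,N#Cc1cc(-c2ccc(O)cc2)cc2ccc(O)c(Br)c12,5.88,6.92,1.00
compound36,Oc1ccc(-c2ccc3cc(O)ccc3c2)cc1,5.68,6.79,1.08
compound37,N#Cc1cc(-c2ccc(O)c(F)c2)nc2ccc(O)cc12,4.98,6.64,1.65
compound38,Oc1ccc(-c2ccc3c(Cl)c(O)ccc3c2)cc1Cl,5.45,6.49,1.01
compound39,C=Cc1cc(-c2ccc(O)c(F)c2)nc2ccc(O)cc12,5.41,6.36,0.89
compound40,N#Cc1cc(-c2cc(F)c(O)c(F)c2)cc2ccc(O)cc12,5.26,6.24,0.93
compound41,C#Cc1cc(-c2ccc(O)cc2)nc2ccc(O)cc12,4.82,6.12,1.28
compound42,Oc1ccc(-c2ccc3c(Br)c(O)ccc3n2)cc1,4.94,6.06,1.08
compound43,Oc1ccc(-c2ccc3cc(O)ccc3n2)cc1,4.75,5.77,0.97
compound44,Oc1cccc(-c2ccc3c(O)cccc3c2)c1,4.84,5.69,0.78
compound45,CC(=O)c1cc(-c2ccc(O)cc2)nc2ccc(O)cc12,4.50,5.66,1.12
compound46,Oc1ccc2cc(-c3ccccc3)ccc2c1,4.87,5.43,0.41
compound47,CC#Cc1cc(-c2ccc(O)c(F)c2)cc2ccc(O)cc12,5.46,7.00,1.52
compound48,N#Cc1cc(-c2ccc(O)c(F)c2)cc2ccc(O)c(Cl)c12,5.52,6.96,1.42
compound49,Oc1ccc(-c2ccc3c(Br)c(O)ccc3c2)cc1,5.58,6.89,1.29
compound50,Cc1c(O)ccc2cc(-c3ccc(O)cc3)ccc12,5.55,6.77,1.19
compound51,Oc1ccc(-c2ccc3cc(O)ccc3n2)cc1,5.20,6.52,1.30
compound52,Oc1ccc2nc(-c3cc(F)c(O)c(F)c3)cc(Br)c2c1,5.11,6.44,1.32
compound53,CCc1cc(-c2ccc(O)cc2)nc2ccc(O)cc12,5.20,6.28,1.05
compound54,C=Cc1cc(-c2ccc(O)cc2)nc2ccc(O)cc12,5.30,6.22,0.87
compound55,CCc1cc(-c2ccc(O)c(F)c2)nc2ccc(O)cc12,4.76,6.10,1.33
compound56,COc1c(O)ccc2cc(-c3ccc(O)cc3)ccc12,5.05,5.94,0.83
compound57,O=[N+]([O-])c1c(O)ccc2cc(-c3ccc(O)cc3)ccc12,5.15,5.70,0.41
compound58,Oc1ccc2nc(-c3ccc(O)c(F)c3)cc(-c3ccccc3)c2c1,4.74,5.68,0.88
compound59,Oc1ccc(-c2ccc3ccccc3c2)cc1,5.20,5.61,0.21
compound60,Oc1cccc(-c2ccc3ccc(O)cc3c2)c1,4.58,5.25,0.56
compound61,Oc1ccc(-c2ccc3c(-c4ccccc4)c(O)ccc3c2)cc1,4.91,5.13,-0.19
compound62,COc1cc(-c2ccc(O)cc2)nc2ccc(O)cc12,4.18,4.92,0.66
compound63,CC(O)c1cc(-c2ccc(O)c(O)c2)nc2ccc(O)cc12,4.30,4.30,
compound64,Oc1ccc(-c2ccc3c(Cl)c(O)ccc3c2)c(F)c1,6.24,7.92,1.68
compound65,Oc1cc(F)c(-c2ccc3cc(O)ccc3c2)c(F)c1,6.99,7.64,0.54
compound66,N#Cc1cc(O)c(Cl)c2ccc(-c3ccc(O)cc3)cc12,6.01,7.52,1.50
compound67,C=Cc1cc(-c2ccc(O)c(F)c2)cc2ccc(O)cc12,5.60,7.36,1.75
compound68,N#Cc1cc(-c2ccc(O)cc2)cc2ccc(O)c(Cl)c12,5.96,7.22,1.23
compound69,Oc1ccc2cc(-c3ccc(O)c(Cl)c3)ccc2c1,5.97,6.96,0.94
compound70,COc1cc(O)ccc1-c1ccc2cc(O)ccc2c1,5.76,6.57,0.74
compound71,CC(=O)c1cc(-c2ccc(O)c(F)c2)nc2ccc(O)cc12,4.47,6.03,1.55
compound72,C#Cc1cc(-c2cc(F)c(O)c(F)c2)nc2ccc(O)cc12,4.32,5.12,0.73
compound73,Oc1ccc2cc(-c3ccccc3O)ccc2c1,4.30,4.70,0.18
compound74,Oc1ccc(-c2ccc3cc(O)ccc3c2)c(F)c1,6.62,7.70,1.04
compound75,CCc1cc(O)cc2ccc(-c3ccc(O)c(F)c3)cc12,5.95,7.60,1.65
compound76,O=Cc1cc(-c2ccc(O)c(F)c2)cc2ccc(O)cc12,5.64,7.47,1.83
compound77,N#Cc1cc(-c2ccc(O)c(F)c2)cc2ccc(O)c(F)c12,5.51,7.25,1.74
compound78,C#Cc1cc(-c2ccc(O)c(F)c2)cc2ccc(O)cc12,5.61,7.20,1.58
compound79,Cc1cc(O)ccc1-c1ccc2c(Cl)c(O)ccc2c1,6.40,6.89,0.32
compound80,N#Cc1cc(-c2ccc(O)cc2)nc2ccc(O)cc12,5.34,6.55,1.18
compound81,Oc1ccc2ccc(-c3ccccc3)cc2c1,4.47,5.28,0.74
compound82,O=c1c(-c2ccc(O)cc2)coc2cc(O)cc(O)c12,5.40,7.01,1.60
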