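disease,dalys_thousands,drivers,scores,taxon
Human Immunodeficiency Virus,81547,,,V
Tuberculosis,49396,Alt,80,B
Rotaviral enteritis,18650,"EWE, M, P, R","20, 20, 20, 20",V
Escherichia coli,14436,"Alt, EWE, R, W","80, 40 + 12.5, 80, 80",B
Typhoid and Paratyphoid fever,12239,"M, P, R, T","60, 80, 20, 20",B
Measles,10420,,,V
Syphilis,9578,,,B
Cryptosporidiosis,8372,"EWE, P, R, S, T","80, 60, 60, 60, 80",P
Campylobacter enteritis,7541,"M, R, T","60, 20, 60",B
Shigellosis,7052,"EWE, R","80, 20 + 20",B
Pertussis,7018,,,B
Meningitis (Neisseria meningitidis),5163,"M, P","80, 80",B
Salmonella enterica (Non typhoidal),4847,P,20,B
Hepatitis B,4674,R,20,V
Cholera,4463,"CC, EWE, M, O, P, R, S, T, W","5, 80, 22.5, 15, 80, 20, 80, 20, 40",B
Hepatitis A,4351,"EWE, O, R","30, 20, 20",V
Hepatitis E,3715,"EWE, R","20, 20",V
Amoebiasis,2237,"CC, M, R","5, 60, 20",P
Rabies,1462,"Alt, R","20, 50",V
Chlamydia,714,"Alt, EWE, M, R","80, 40, 50, 50",B
Varicella (Chicken pox & Herpes zoster),581,M,20,V
Hepatitis C,518,,,V
Trachoma,334,"Alt, EWE","80 + 80, 80",B
Gonorrhea,282,,,B
Trichomoniasis,167,,,P
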