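gene_name,gene_id,gene_symbol,arabidopsis_locus,primer_pair,amplicon_bp,efficiency,r_squared,is_candidate_reference
Glyceraldehyde-3-phosphate dehydrogenase,CL7040.Contig2_All,GAPDH,AT1G13440,AAATTAAGGCTGCAATCAAGCAAGCCACAAGCTTCACAAAGT,169,1.874,0.9992,true
Actin,CL1144.Contig2_All,ACT,AT3G18780,CAAATCATGTTCGAGACCTTCAAGACGAAGAATGGCATGGGGA,173,1.873,0.9989,true
Ubiquitin-conjugating enzyme,CL5627.Contig8_All,UBC,AT4G27960,TGCCTTGACCATCTCCAAGGTTCTCAACTATCCATCCGCTCACCC,200,1.865,0.9995,true
Elongation factor 1-alpha,CL3597.Contig3_All,EF1-alpha,AT1G07920,AAGGATGGGCAGACCCGTGAGCACCAACCTTCTTGAGGTAGGAAG,161,1.823,0.9991,true
alpha-tubulin,CL544.Contig2_All,alpha-TUB,AT1G50010,TGTGCATTGGTATGTTGGTGAGTCATCCCCCTCGTCACCCTC,139,1.872,0.9994,true
beta-tubulin,Unigene13345_All,beta-TUB,AT5G12250,TATCAACAGTATCAGGATGCGACCGAACAATCAAAACCACCATAA,213,1.853,0.9995,true
Serine/threonine-protein phosphatase PP2A,CL6570.Contig3_All,PP2A,AT1G13320,GTACCGAACATTAAATTCAATCTTGATTTGCAAAATATCTGAC,176,1.863,0.9994,true
Expressed protein 1,CL7794.Contig1_All,EXP1,AT2G32170,ATTGAAACAACCTACACCGCAAGCTGTAAGAATGCTAATCGTTCA,133,1.872,0.9995,true
Polypyrimidine tract-binding protein 1,CL6418.Contig1_All,PTBP1,AT3G01150,GCAATTTTTGAGAAGAATGGTGGACAGATGAAGCTTACAGTAAC,131,1.876,0.9996,true
Expressed protein 2,CL670.Contig8_All,EXP2,AT4G33380,AAACATCAAGAGTGCTGGCTTGCATGCATAGAGTGATTAC,198,1.779,0.9996,true
TIP41-like protein,Unigene3100_All,TIP41,AT4G34270,GCAACCATCCAAAGTTTAACTGCTAATGTGCAAGCAGGGCTAGTAA,157,1.847,0.9996,true
Cyclophilin 1,CL6321.Contig1_All,CYP1,AT2G16600,TCGTGAGGGCCATCGAGAAGGTCTCATAACAAACAGACCATTATT,137,1.819,0.9997,true
Cyclophilin 2,CL8032.Contig1_All,CYP2,AT4G33060,TCCCGATTCTTCTGGAAAGGAAGCCTTGTCTGGTAGAACAGC,181,1.880,0.9996,true
Mitosis protein YLS8,CL7523.Contig2_All,YLS8,AT5G08290,CGACTGGGACGAAACCTGCATGCGGATCGTACGCTCGTACATTG,138,1.775,0.9996,true
Secologanin synthase,CL4267.Contig5_All,CYP72A1,AT3G14690,TTCACTCTCCCTTCTCCTTTAGCACCGATTTCCTCTTTCAT,150,1.820,0.9996,false
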