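pathway	n	p_SPL	p_LPL	p_CRC
KEGG BASE EXCISION REPAIR	48	0.042	-	-
KEGG HOMOLOGOUS RECOMBINATION	34	0.043	-	-
REACTOME ACTIVATION OF THE PRE REPLICATIVE COMPLEX	35	0.047	-	-
REACTOME HOMOLOGOUS RECOMBINATION REPAIR	22	-	0.048	-
BIOCARTA CELLCYCLE PATHWAY	32	-	-	0.025
BIOCARTA MONOCYTE PATHWAY	20	-	-	0.035
BIOCARTA P27 PATHWAY	14	-	-	0.025
BIOCARTA RB PATHWAY	20	-	-	0.047
BIOCARTA SET PATHWAY	15	-	-	0.034
BIOCARTA SKP2E2F PATHWAY	12	-	-	0.014
KEGG RNA POLYMERASE	27	-	-	0.04
REACTOME AMINO ACID TRANSPORT ACROSS THE PLASMA MEMBRANE	40	-	-	0.027
REACTOME CYTOSOLIC TRNA AMINOACYLATION	26	-	-	0.031
REACTOME G1 PHASE	17	-	-	0.03
REACTOME GLUCOSE TRANSPORT	55	-	-	0.041
REACTOME GLYCOLYSIS	27	-	-	0.039
REACTOME NEP NS2 INTERACTS WITH THE CELLULAR EXPORT MACHINERY	39	-	-	0.049
REACTOME POST CHAPERONIN TUBULIN FOLDING PATHWAY	9	-	-	0.034
REACTOME PREFOLDIN MEDIATED TRANSFER OF SUBSTRATE TO CCT TRIC	25	-	-	0.027
REACTOME PROSTANOID HORMONES	15	-	-	0.046
REACTOME RNA POLYMERASE III CHAIN ELONGATION	12	-	-	0.033
REACTOME RNA POLYMERASE III TRANSCRIPTION INITIATION FROM TYPE 2 PROMOTER	21	-	-	0.047
REACTOME TAT MEDIATED HIV1 ELONGATION ARREST AND RECOVERY	31	-	-	0.049
REACTOME TRNA AMINOACYLATION	34	-	-	0.048
REACTOME TRANSPORT OF RIBONUCLEOPROTEINS INTO THE HOST NUCLEUS	40	-	-	0.043
REACTOME VPR MEDIATED NUCLEAR IMPORT OF PICS	48	-	-	0.031
SA REG CASCADE OF CYCLIN EXPR	18	-	-	0.01
BIOCARTA ARF PATHWAY	24	0.033	0.037	-
KEGG NUCLEOTIDE EXCISION REPAIR	48	0.031	0.043	-
KEGG ONE CARBON POOL BY FOLATE	19	0.004	0.032	-
REACTOME DUAL INCISION REACTION IN GG NER	18	0.032	0.025	-
REACTOME G2 M TRANSITION	80	0.038	0.035	-
REACTOME MITOCHONDRIAL TRNA AMINOACYLATION	11	0.032	0.04	-
REACTOME PURINE METABOLISM	42	0.037	0.03	-
REACTOME RNA POLYMERASE I CHAIN ELONGATION	29	0.021	0.026	-
REACTOME RNA POLYMERASE I PROMOTER ESCAPE	21	0.027	0.014	-
REACTOME RNA POLYMERASE I TRANSCRIPTION INITIATION	25	0.013	0.009	-
REACTOME RNA POLYMERASE I TRANSCRIPTION TERMINATION	22	0.027	0.013	-
REACTOME SNRNP ASSEMBLY	60	0.031	0.029	-
REACTOME MRNA DECAY BY 3 TO 5 EXORIBONUCLEASE	11	0.015	-	0.029
REACTOME RNA POLYMERASE III TRANSCRIPTION INITIATION	29	0.041	-	0.047
REACTOME NUCLEAR IMPORT OF REV PROTEIN	39	-	0.049	0.043
REACTOME REV MEDIATED NUCLEAR EXPORT OF HIV1 RNA	41	-	0.043	0.039
BIOCARTA PTC1 PATHWAY	13	0.022	0.018	0.028
BIOCARTA RANMS PATHWAY	8	0.013	0.024	0.022
REACTOME CYCLIN A1 ASSOCIATED EVENTS DURING G2 M TRANSITION	19	0.038	0.034	0.026
REACTOME FORMATION OF TUBULIN FOLDING INTERMEDIATES BY CCT TRIC	18	0.044	0.039	0.011
REACTOME PURINE RIBONUCLEOSIDE MONOPHOSPHATE BIOSYNTHESIS	13	0	0.004	0.008
REACTOME REGULATION OF GLUCOKINASE BY GLUCOKINASE REGULATORY PROTEIN	42	0.044	0.031	0.044
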