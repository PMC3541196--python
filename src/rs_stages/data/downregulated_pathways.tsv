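pathway	n	p_SPL	p_LPL	p_CRC
BIOCARTA AT1R PATHWAY	50	0.047	-	-
BIOCARTA BIOPEPTIDES PATHWAY	81	0.027	-	-
BIOCARTA IL3 PATHWAY	20	0.044	-	-
KEGG ALDOSTERONE REGULATED SODIUM REABSORPTION	51	0.029	-	-
KEGG CHEMOKINE SIGNALING PATHWAY	216	0.042	-	-
KEGG GAP JUNCTION	100	0.039	-	-
KEGG MAPK SIGNALING PATHWAY	400	0.047	-	-
KEGG VASCULAR SMOOTH MUSCLE CONTRACTION	152	0.037	-	-
REACTOME FORMATION OF PLATELET PLUG	236	0.017	-	-
REACTOME FRS2 MEDIATED ACTIVATION	23	0.049	-	-
REACTOME HEMOSTASIS	348	0.024	-	-
REACTOME METABOLISM OF LIPIDS AND LIPOPROTEINS	256	0.046	-	-
REACTOME NRAGE SIGNALS DEATH THROUGH JNK	61	0.041	-	-
REACTOME PLATELET ACTIVATION	208	0.018	-	-
REACTOME RHO GTPASE CYCLE	132	0.046	-	-
REACTOME SEMAPHORIN INTERACTIONS	89	0.031	-	-
SA PTEN PATHWAY	27	0.027	-	-
REACTOME CAM PATHWAY	32	-	0.042	-
REACTOME G ALPHA Z SIGNALLING EVENTS	13	-	0.04	-
REACTOME G BETA GAMMA SIGNALLING THROUGH PLC BETA	23	-	0.037	-
REACTOME G PROTEIN ACTIVATION	34	-	0.02	-
REACTOME NEURORANSMITTER RECEPTOR BINDING AND DOWNSTREAM TRANSMISSION IN THE POSTSYNAPTIC CELL	115	-	0.035	-
BIOCARTA NUCLEARRS PATHWAY	22	-	-	0.009
KEGG ASCORBATE AND ALDARATE METABOLISM	19	-	-	0.008
KEGG DRUG METABOLISM CYTOCHROME P450	71	-	-	0.017
KEGG DRUG METABOLISM OTHER ENZYMES	51	-	-	0.045
KEGG LONG TERM POTENTIATION	94	-	-	0.024
KEGG METABOLISM OF XENOBIOTICS BY CYTOCHROME P450	69	-	-	0.018
KEGG NICOTINATE AND NICOTINAMIDE METABOLISM	26	-	-	0.047
KEGG PENTOSE AND GLUCURONATE INTERCONVERSIONS	24	-	-	0.009
KEGG NITROGEN METABOLISM	28	-	-	0.024
KEGG RETINOL METABOLISM	59	-	-	0.028
KEGG STARCH AND SUCROSE METABOLISM	54	-	-	0.014
REACTOME ACTIVATION OF NMDA RECEPTOR UPON GLUTAMATE BINDING AND POSTSYNAPTIC EVENTS	62	-	-	0.049
REACTOME ETHANOL OXIDATION	8	-	-	0.012
REACTOME GLUCURONIDATION	15	-	-	0
REACTOME MITOCHONDRIAL FATTY ACID BETA OXIDATION	9	-	-	0.039
REACTOME PHASE II CONJUGATION	62	-	-	0.036
BIOCARTA HDAC PATHWAY	44	0.022	0.041	-
KEGG GLYCOSPHINGOLIPID BIOSYNTHESIS LACTO AND NEOLACTO SERIES	37	0.041	0.037	-
REACTOME ACTIVATION OF KAINATE RECEPTORS UPON GLUTAMATE BINDING	37	0.022	0.01	-
REACTOME ADP SIGNALLING THROUGH P2Y PURINOCEPTOR 1	31	0.01	0.01	-
REACTOME ADP SIGNALLING THROUGH P2Y PURINOCEPTOR 12	24	0.028	0.021	-
REACTOME GLUCAGON SIGNALING IN METABOLIC REGULATION	42	0.046	0.028	-
REACTOME GLUCAGON TYPE LIGAND RECEPTORS	39	0.042	0.036	-
REACTOME GS ALPHA MEDIATED EVENTS IN GLUCAGON SIGNALLING	30	0.015	0.012	-
REACTOME G BETA GAMMA SIGNALLING THROUGH PI3KGAMMA	30	0.034	0.027	-
REACTOME HORMONE SENSITIVE LIPASE HSL MEDIATED TRIACYLGLYCEROL HYDROLYSIS	18	0.045	0.042	-
REACTOME IONOTROPIC ACTIVITY OF KAINATE RECEPTORS	14	0.049	0.018	-
REACTOME OTHER SEMAPHORIN INTERACTIONS	25	0.005	0.005	-
REACTOME PLATELET ACTIVATION TRIGGERS	73	0.028	0.047	-
REACTOME SIGNAL AMPLIFICATION	39	0.007	0.005	-
REACTOME THROMBIN SIGNALLING THROUGH PROTEINASE ACTIVATED RECEPTORS	28	0.019	0.016	-
REACTOME THROMBOXANE SIGNALLING THROUGH TP RECEPTOR	26	0.007	0.003	-
KEGG GNRH SIGNALING PATHWAY	150	0.017	-	0.008
BIOCARTA STATHMIN PATHWAY	34	-	0.034	0.009
BIOCARTA PGC1A PATHWAY	37	0.005	0.011	0.008
KEGG PPAR SIGNALING PATHWAY	86	0.026	0.034	0.044
KEGG PROXIMAL TUBULE BICARBONATE RECLAMATION	25	0.003	0.003	0.011
KEGG SULFUR METABOLISM	18	0.047	0.03	0.038
REACTOME NUCLEAR RECEPTOR TRANSCRIPTION PATHWAY	78	0.005	0.006	0.006
REACTOME NUCLEOTIDE LIKE PURINERGIC RECEPTORS	23	0.011	0.012	0.022
REACTOME P2Y RECEPTORS	18	0.009	0.01	0.036
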