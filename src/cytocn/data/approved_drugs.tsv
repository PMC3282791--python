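gene	cytoband	event	drug	type	status	indication
ADA	20q13.11-20q13.12	AMP	Cladribine	inhibitor	approved	Hairy cell leukemia
ADA	20q13.11-20q13.12	AMP	Dipyridamole	inhibitor	approved	Platelet inhibitor
ADA	20q13.11-20q13.12	AMP	Fludarabine	inhibitor	approved	Hematological malignancies
ADA	20q13.11-20q13.12	AMP	Pentostatin	inhibitor	approved	Hairy cell leukemia
CHRNA4	20q13.33	AMP	Pentolinium	antagonist	approved	Hypotension
CHRNA4	20q13.33	AMP	Trimethaphan	antagonist	approved	Hypertensive emergencies
CYP11B1	8q24.3	AMP	Metyrapone	inhibitor	approved	Cushing's syndrome (hypercortisolism)
DGAT1	8q24.3	AMP	Hesperetin	inhibitor	approved	High cholesterol levels
EDNRB	13q22.3-13q31.1	AMP	Bosentan	antagonist	approved	Pulmonary arterial hypertension
FLT1	13q12.3	AMP	Ranibizumab	inhibitor	approved	Age-related macular degeneration, diabetic macular edema, and retinal vein occlusion
FLT1	13q12.3	AMP	Sorafenib	inhibitor	approved	NSCLC; melanoma; Myelodyspalstic syndrome; AML; head and neck, breast, colon, ovarian, pancreatic, renal, hepatic cancer
FLT3	13q12.2	AMP	Sunitinib	inhibitor	approved	Advanced renal cell carcinoma
GHR	5p12	AMP	Pegvisomant	antagonist	approved	Acromegaly
HTR2A	13q14.12-13q21.1	AMP	Asenapine	antagonist	approved	Schizophrenia and bipolar disorder
HTR2A	13q14.12-13q21.1	AMP	Iloperidone	antagonist	approved	Schizophrenia
HTR2A	13q14.12-13q21.1	AMP	Sarpogrelate	antagonist	approved	Diabetes mellitus
SQLE	8q24.13	AMP	Butenafine	inhibitor	approved	Dermatologic infections
SQLE	8q24.13	AMP	Naftifine	inhibitor	approved	Fungal infections
SQLE	8q24.13	AMP	Terbinafine	inhibitor	approved	Fungal infections
SQLE	8q24.13	AMP	Tolnaftate	inhibitor	approved	Jock itch, athlete's foot
SRC	20q11.23	AMP	Dasatinib	inhibitor	approved	Chronic myelogenous leukemia, solid tumours, multiple myeloma
SRC	20q11.23	AMP	Herbimycin A	inhibitor	approved	Cancer
TNFSF11	13q14.11	AMP	Denosumab	antibody	approved	Postmenopausal osteoporosis, rheumatoid arthritis, bone metastases in prostate cancer
TOP1	20q12	AMP	Irinotecan	inhibitor	approved	Colorectal Cancer
TOP1	20q12	AMP	Topetecan	inhibitor	approved	Small cell lung cancer, second-line therapy; ovarian cancer
FECH	18q21.31	DEL	Methyl aminolevulinate	activator	approved	Photodynamic therapy
KRT16P2	17p11.2	DEL	Griseofulvin	inducer	approved	Ringworm infections
LPL	8p22-8p21.3	DEL	Clofibrate	activator	approved	Dysbetalipoproteinemia
LPL	8p22-8p21.3	DEL	Gemfibrozil	activator	approved	Hyperlipidemia
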