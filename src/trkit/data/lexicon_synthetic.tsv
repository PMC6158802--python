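surface	concept_id	preferred_name	category
ceritinib	NCIT:C95703	Ceritinib	DRUG
crizotinib	NCIT:C74061	Crizotinib	DRUG
alectinib	NCIT:C101790	Alectinib	DRUG
lorlatinib	NCIT:C113655	Lorlatinib	DRUG
brigatinib	NCIT:C98831	Brigatinib	DRUG
vemurafenib	NCIT:C64768	Vemurafenib	DRUG
dabrafenib	NCIT:C82386	Dabrafenib	DRUG
trametinib	NCIT:C77908	Trametinib	DRUG
cobimetinib	NCIT:C68923	Cobimetinib	DRUG
erlotinib	NCIT:C65530	Erlotinib	DRUG
gefitinib	NCIT:C1855	Gefitinib	DRUG
osimertinib	NCIT:C116377	Osimertinib	DRUG
afatinib	NCIT:C66940	Afatinib	DRUG
imatinib	NCIT:C62035	Imatinib	DRUG
sunitinib	NCIT:C71622	Sunitinib	DRUG
sorafenib	NCIT:C61948	Sorafenib	DRUG
nivolumab	NCIT:C68814	Nivolumab	DRUG
pembrolizumab	NCIT:C106432	Pembrolizumab	DRUG
ipilimumab	NCIT:C2654	Ipilimumab	DRUG
trastuzumab	NCIT:C1647	Trastuzumab	DRUG
cetuximab	NCIT:C1723	Cetuximab	DRUG
panitumumab	NCIT:C1857	Panitumumab	DRUG
olaparib	NCIT:C71721	Olaparib	DRUG
palbociclib	NCIT:C49176	Palbociclib	DRUG
larotrectinib	NCIT:C125037	Larotrectinib	DRUG
entrectinib	NCIT:C98596	Entrectinib	DRUG
selpercatinib	NCIT:C134987	Selpercatinib	DRUG
capmatinib	NCIT:C116722	Capmatinib	DRUG
ALK	NCIT:C21213	ALK Gene	GENE
EGFR	NCIT:C17068	EGFR Gene	GENE
BRAF	NCIT:C17476	BRAF Gene	GENE
KRAS	NCIT:C25785	KRAS Gene	GENE
NRAS	NCIT:C17394	NRAS Gene	GENE
EIF2AK3	NCIT:C26354	EIF2AK3 Gene	GENE
ROS1	NCIT:C91265	ROS1 Gene	GENE
MET	NCIT:C18324	MET Gene	GENE
ERBB2	NCIT:C17319	ERBB2 Gene	GENE
HER2	NCIT:C17319	ERBB2 Gene	GENE
RET	NCIT:C18259	RET Gene	GENE
NTRK1	NCIT:C17329	NTRK1 Gene	GENE
KIT	NCIT:C17250	KIT Gene	GENE
PDGFRA	NCIT:C18631	PDGFRA Gene	GENE
PIK3CA	NCIT:C20176	PIK3CA Gene	GENE
TP53	NCIT:C17359	TP53 Gene	GENE
BRCA1	NCIT:C17965	BRCA1 Gene	GENE
BRCA2	NCIT:C18009	BRCA2 Gene	GENE
CDKN2A	NCIT:C17783	CDKN2A Gene	GENE
PTEN	NCIT:C17331	PTEN Gene	GENE
IDH1	NCIT:C95003	IDH1 Gene	GENE
FGFR2	NCIT:C18422	FGFR2 Gene	GENE
fusion	NCIT:C20195	Gene Fusion	ALTERATION
rearrangement	NCIT:C36541	Gene Rearrangement	ALTERATION
mutation	NCIT:C45576	Mutation	ALTERATION
amplification	NCIT:C16605	Gene Amplification	ALTERATION
deletion	NCIT:C16606	Gene Deletion	ALTERATION
overexpression	NCIT:C18254	Overexpression	ALTERATION
loss	NCIT:C117973	Gene Loss	ALTERATION
V600E	NCIT:C98283	BRAF V600E Mutation	ALTERATION
T790M	NCIT:C98284	EGFR T790M Mutation	ALTERATION
exon 19 deletion	NCIT:C98285	EGFR Exon 19 Deletion	ALTERATION
NSCLC	NCIT:C2926	Non-Small Cell Lung Carcinoma	DISEASE
non-small cell lung cancer	NCIT:C2926	Non-Small Cell Lung Carcinoma	DISEASE
lung cancer	NCIT:C4878	Lung Carcinoma	DISEASE
melanoma	NCIT:C3224	Melanoma	DISEASE
breast cancer	NCIT:C4872	Breast Carcinoma	DISEASE
colorectal cancer	NCIT:C2955	Colorectal Carcinoma	DISEASE
gastric cancer	NCIT:C4911	Gastric Carcinoma	DISEASE
glioblastoma	NCIT:C3058	Glioblastoma	DISEASE
pancreatic cancer	NCIT:C3850	Pancreatic Carcinoma	DISEASE
ovarian cancer	NCIT:C4908	Ovarian Carcinoma	DISEASE
prostate cancer	NCIT:C4863	Prostate Carcinoma	DISEASE
thyroid cancer	NCIT:C4815	Thyroid Carcinoma	DISEASE
cholangiocarcinoma	NCIT:C4436	Cholangiocarcinoma	DISEASE
sarcoma	NCIT:C9118	Sarcoma	DISEASE
leukemia	NCIT:C3161	Leukemia	DISEASE
lymphoma	NCIT:C3208	Lymphoma	DISEASE
biopsy	NCIT:C15189	Biopsy	PROCEDURE
radiotherapy	NCIT:C15313	Radiation Therapy	PROCEDURE
surgery	NCIT:C15329	Surgical Procedure	PROCEDURE
acupuncture	NCIT:C15184	Acupuncture	PROCEDURE
blueberries	NCIT:C71481	Blueberry	FOOD
green tea	NCIT:C855	Green Tea	FOOD
turmeric	NCIT:C91364	Turmeric	FOOD
randomized controlled trial	NCIT:C15417	Randomized Controlled Trial	OTHER
clinical trial	NCIT:C71104	Clinical Trial	OTHER
case report	NCIT:C49152	Case Report	OTHER
clinical series	NCIT:C15206	Clinical Series	OTHER
meta-analysis	NCIT:C17886	Meta-Analysis	OTHER
cell line	NCIT:C16403	Cell Line	OTHER
mouse model	NCIT:C14238	Mouse Model	OTHER
in vitro	NCIT:C28239	In Vitro	OTHER
in vivo	NCIT:C28240	In Vivo	OTHER
tumor	NCIT:C3262	Neoplasm	OTHER
patients	NCIT:C16960	Patient	OTHER
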