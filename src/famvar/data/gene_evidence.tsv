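gene	human_chd_reported	mouse_model_chd	cardiac_development_role	nhomalt	refs
CASZ1	1	1	1		VSD/DCM/LVNC associations;Casz1 knockout mice
ROCK1	1	1	1		left-sided CHD cohort;Rock1 dominant-negative NCC valve defects
MCTP2	1	0	1		15q26.2 deletions with COA;Xenopus knockdown endocardial cushion defect
ROBO4	1	0	1		BAV association;endothelial guidance receptor
CTBP2	1	0	1		CHD cohort report;EMT transcriptional repressor
SMYD1	1	1	1		heterotaxy splicing variant;Smyd1 null single ventricle
BMP10	1	1	1		CHD cohort report;Bmp10 null cardiac growth defect
MYH6	1	1	1		COA risk variant in Iceland;sarcomeric cardiomyopathy models
MATR3	1	1	1		CHD association;Matr3 mouse model
NOTCH1	1	1	1		BAV/AVS familial CHD;Notch1 mouse models
HEY1	0	1	1		Hey1/HeyL double knockout VSD and valve dysplasia
ELN	1	1	0	2	supravalvar aortic stenosis;Eln null obstructive arterial disease
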