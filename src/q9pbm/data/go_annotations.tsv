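# Gene Ontology classification of the candidate OsSMF1 target genes.
# One row per (term, gene) association; genes may appear under several terms.
go_id	go_name	namespace	gene_id
GO:0045735	nutrient reservoir activity	molecular_function	Os01g0762500
GO:0045735	nutrient reservoir activity	molecular_function	Os10g0400200
GO:0045735	nutrient reservoir activity	molecular_function	Os03g0427300
GO:0045735	nutrient reservoir activity	molecular_function	Os02g0268300
GO:0045735	nutrient reservoir activity	molecular_function	Os02g0268100
GO:0045735	nutrient reservoir activity	molecular_function	Os05g0499100
GO:0051171	regulation of nitrogen compound metabolic process	biological_process	Os07g0182000
GO:0051171	regulation of nitrogen compound metabolic process	biological_process	Os01g0393100
GO:0051171	regulation of nitrogen compound metabolic process	biological_process	Os05g0404700
GO:0051171	regulation of nitrogen compound metabolic process	biological_process	Os04g0629300
GO:0051171	regulation of nitrogen compound metabolic process	biological_process	Os05g0415400
GO:0051171	regulation of nitrogen compound metabolic process	biological_process	Os03g0799600
GO:0051171	regulation of nitrogen compound metabolic process	biological_process	Os04g0437000
GO:0051171	regulation of nitrogen compound metabolic process	biological_process	Os09g0520400
GO:0051171	regulation of nitrogen compound metabolic process	biological_process	Os02g0252400
GO:0051171	regulation of nitrogen compound metabolic process	biological_process	Os07g0668600
GO:0006952	defense response	biological_process	Os11g0582400
GO:0006952	defense response	biological_process	Os11g0701100
GO:0006952	defense response	biological_process	Os03g0179700
GO:0006952	defense response	biological_process	Os02g0268100
GO:0006952	defense response	biological_process	Os02g0268300
GO:0051253	negative regulation of RNA metabolic process	biological_process	Os05g0404700
GO:0051253	negative regulation of RNA metabolic process	biological_process	Os03g0799600
GO:0051253	negative regulation of RNA metabolic process	biological_process	Os04g0629300
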