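# SYNTHETIC per-patient phenotype matrix. Only the two index patients' columns
# are published per patient; the remaining rows are a synthetic reconstruction
# chosen to reproduce the published aggregate counts exactly (see
# table_phenotype_counts.tsv). Cell vocabulary: + / - / n.a.
patient_id	prenatal_complications	neonatal_complications	hypotonia	developmental_delay	epilepsy	abnormal_movements	facial_dysmorphism	cardiac	genitourinary	ocular	skeletal	teeth	git_issues	increased_serum_alp	hyperckemia_rhabdomyolysis
P1	+	+	+	+	+	+	+	+	-	+	+	+	-	+	+
P2	+	+	+	+	+	+	+	-	-	+	+	+	+	n.a.	-
P3	+	+	+	+	+	+	+	+	+	+	+	+	+	+	n.a.
P4	+	+	+	+	+	+	+	+	+	+	+	+	+	+	n.a.
P5	+	+	+	+	+	+	+	+	+	+	+	+	+	+	n.a.
P6	-	+	+	+	+	+	+	+	+	+	+	-	+	+	n.a.
P7	-	+	+	+	+	+	+	+	+	+	+	-	+	-	n.a.
P8	-	+	+	+	+	+	+	+	+	+	+	-	+	-	n.a.
P9	-	+	+	+	+	+	+	+	+	+	+	-	+	-	n.a.
P10	-	-	+	+	+	+	+	-	-	+	-	-	+	n.a.	n.a.
P11	-	-	+	+	+	-	+	-	-	+	-	n.a.	n.a.	n.a.	n.a.
P12	-	-	n.a.	+	n.a.	n.a.	+	-	n.a.	+	-	n.a.	n.a.	n.a.	n.a.
P13	n.a.	n.a.	n.a.	n.a.	n.a.	n.a.	n.a.	n.a.	n.a.	n.a.	n.a.	n.a.	n.a.	n.a.	n.a.
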