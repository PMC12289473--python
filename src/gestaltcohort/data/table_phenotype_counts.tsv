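# Published aggregate phenotype counts for the 13-patient cohort.
# percent = floor(100 * numerator / denominator); the gender pair is printed as
# complementary percents (female floor, male 100 - floor).
feature	numerator	denominator	n_na	percent
gender_female	5	12	1	41
gender_male	7	12	1	59
prenatal_complications	5	12	1	41
neonatal_complications	9	12	1	75
hypotonia	11	11	2	100
developmental_delay	12	12	1	100
epilepsy	11	11	2	100
abnormal_movements	10	11	2	90
facial_dysmorphism	12	12	1	100
cardiac	8	12	1	66
genitourinary	7	11	1	63
ocular	12	12	1	100
skeletal	9	12	1	75
teeth	5	10	3	50
git_issues	9	10	3	90
increased_serum_alp	5	8	5	62
hyperckemia_rhabdomyolysis	1	2	11	50
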