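id	mature_seq	mature_len	arm	nm_vs_homolog	precursor_len	chrom	start	end	strand	u_content	mfe	mfei	nm_star	gu_pairs
miR166v	UCGGACCAGGCUUCAUUCCCC	21	3p	0	98	Chr06	12993098	12993196	-	0.273	-46.60	0.93	3	2
miR166w	UCGGACCAGGCUUCAUUCCCC	21	3p	0	147	Chr01	26215701	26215847	-	0.252	-46.30	0.71	4	2
miR166x	UCGGACCAGGCUUCAUUCCCC	21	3p	0	103	Chr08	282648	282750	-	0.272	-46.20	0.92	3	2
miR166y	UCGGACCAGGCUUCAUUCCCC	21	3p	0	102	Chr05	37747460	37747561	-	0.414	-90.70	1.35	2	3
miR166z	UCUCGGACCAGGCUUCAUUCC	21	3p	0	244	Chr16	3661371	3661614	+	0.255	-46.00	0.90	3	2
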