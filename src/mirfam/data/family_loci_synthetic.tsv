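# SYNTHETIC reconstruction of the 26-member soybean MIR166 family layout.
# The five novel precursors (miR166v-z) carry their published genomic
# coordinates; the 21 known members (a-u) are placed to be consistent with
# the published facts -- per-chromosome counts (Chr06:4, Chr04:3, Chr08:3,
# Chr05/07/09/10/16: 2 each, Chr01/02/03/15/19/20: 1 each), the four
# same-strand cluster pairings (v/o, x/b, y/n, e/q), and intra-cluster gaps
# spanning the published 90-158 nt range -- because the full coordinate
# table of the known members is not bundled.  Non-cluster members are
# placed far apart so no spurious cluster can arise.
id	chrom	start	end	strand
miR166a	Chr06	2100000	2100099	+
miR166b	Chr08	282886	282985	-
miR166c	Chr06	8400000	8400099	-
miR166d	Chr04	1200000	1200099	+
miR166e	Chr04	5000000	5000099	+
miR166f	Chr08	1500000	1500099	+
miR166g	Chr07	3300000	3300099	+
miR166h	Chr07	9900000	9900099	-
miR166i	Chr09	2700000	2700099	+
miR166j	Chr09	8100000	8100099	-
miR166k	Chr10	4200000	4200099	+
miR166l	Chr16	9600000	9600099	-
miR166m	Chr10	7500000	7500099	-
miR166n	Chr05	37747682	37747781	-
miR166o	Chr06	12993287	12993386	-
miR166p	Chr02	6600000	6600099	+
miR166q	Chr04	5000258	5000357	+
miR166r	Chr03	4800000	4800099	-
miR166s	Chr15	5700000	5700099	+
miR166t	Chr19	6000000	6000099	-
miR166u	Chr20	6300000	6300099	+
miR166v	Chr06	12993098	12993196	-
miR166w	Chr01	26215701	26215847	-
miR166x	Chr08	282648	282750	-
miR166y	Chr05	37747460	37747561	-
miR166z	Chr16	3661371	3661614	+
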