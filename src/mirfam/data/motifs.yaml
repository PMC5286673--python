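# Cis-regulatory element catalogue for promoter scanning.
#
# Patterns are editable IUPAC consensi in the PlantCARE style; the element
# names cover the classes commonly profiled for plant MIR gene promoters
# (core elements, light / hormone / seed / stress response, metabolism,
# cell cycle).  `both_strands: false` restricts a motif to the sense strand.
motifs:
  - {name: TATA-box,      pattern: TATAAA,        class: other}
  - {name: CAAT-box,      pattern: CCAAT,         class: other}
  - {name: G-box,         pattern: CACGTG,        class: light}
  - {name: Box4,          pattern: ATTAAT,        class: light}
  - {name: GT1-motif,     pattern: GGTTAA,        class: light}
  - {name: ABRE,          pattern: ACGTGGC,       class: hormone}
  - {name: CGTCA-motif,   pattern: CGTCA,         class: hormone}
  - {name: TCA-element,   pattern: CCATCTTTTT,    class: hormone}
  - {name: ERE,           pattern: ATTTCAAA,      class: hormone}
  - {name: Skn-1_motif,   pattern: GTCAT,         class: seed}
  - {name: GCN4_motif,    pattern: TGAGTCA,       class: seed}
  - {name: RY-element,    pattern: CATGCATG,      class: seed}
  - {name: HD-Zip1,       pattern: CAATWATTG,     class: leaf}
  - {name: TC-rich,       pattern: ATTTTCTTCA,    class: defense/stress}
  - {name: HSE,           pattern: AAAAAATTTC,    class: defense/stress}
  - {name: ARE,           pattern: AAACCA,        class: defense/stress}
  - {name: MBS,           pattern: CAACTG,        class: defense/stress}
  - {name: LTR,           pattern: CCGAAA,        class: defense/stress}
  - {name: O2-site,       pattern: GATGAYRTGR,    class: biosynthesis/metabolism}
  - {name: MBSI,          pattern: AAAAAACSGTTA,  class: biosynthesis/metabolism}
  - {name: MSA-like,      pattern: YCYAACGGY,     class: cell-cycle/circadian}
  - {name: circadian,     pattern: CAANNNNATC,    class: cell-cycle/circadian}
  - {name: HD-ZIPIII-bs,  pattern: GTAATSATTAC,   class: other}
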