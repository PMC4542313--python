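# Default 15-hotspot myeloid leukemia panel.
#
# Genomic coordinates here are synthetic: each hotspot lives on its own
# 300-bp contig with the interrogated codon at positions 150-152 (1-based),
# so the whole pipeline runs without a reference-genome download.  Substitute
# hg19 contigs/positions to run against real alignments.
name: default-hotspot-panel
hotspots:
  - gene: DNMT3A
    codon_label: R882
    contig: DNMT3A_R882
    strand: "+"
    positions: [150, 151, 152]
    ref_bases: CGC
  - gene: JAK2
    codon_label: V617
    contig: JAK2_V617
    strand: "+"
    positions: [150, 151, 152]
    ref_bases: GTC
  - gene: NPM1
    codon_label: L287
    contig: NPM1_L287
    strand: "+"
    positions: [150, 151, 152]
    ref_bases: CTG
    is_indel_locus: true
    # Canonical mutation A: duplication of the TCTG ending at this position;
    # the 4-bp insertion is placed immediately after it.
    insertion_point: 152
  - gene: SRSF2
    codon_label: P95
    contig: SRSF2_P95
    strand: "+"
    positions: [150, 151, 152]
    ref_bases: CCC
  - gene: SF3B1
    codon_label: K666
    contig: SF3B1_K666
    strand: "+"
    positions: [150, 151, 152]
    ref_bases: AAG
  - gene: SF3B1
    codon_label: K700
    contig: SF3B1_K700
    strand: "+"
    positions: [150, 151, 152]
    ref_bases: AAG
  - gene: IDH1
    codon_label: R132
    contig: IDH1_R132
    strand: "+"
    positions: [150, 151, 152]
    ref_bases: CGT
  - gene: IDH2
    codon_label: R140
    contig: IDH2_R140
    strand: "+"
    positions: [150, 151, 152]
    ref_bases: CGG
  - gene: IDH2
    codon_label: R172
    contig: IDH2_R172
    strand: "+"
    positions: [150, 151, 152]
    ref_bases: AGG
  - gene: KRAS
    codon_label: G12
    contig: KRAS_G12
    strand: "+"
    positions: [150, 151, 152]
    ref_bases: GGT
  - gene: NRAS
    codon_label: G12
    contig: NRAS_G12
    strand: "+"
    positions: [150, 151, 152]
    ref_bases: GGT
  - gene: NRAS
    codon_label: Q61
    contig: NRAS_Q61
    strand: "+"
    positions: [150, 151, 152]
    ref_bases: CAA
  - gene: KIT
    codon_label: D816
    contig: KIT_D816
    strand: "+"
    positions: [150, 151, 152]
    ref_bases: GAC
  - gene: FLT3
    codon_label: D835
    contig: FLT3_D835
    strand: "+"
    positions: [150, 151, 152]
    ref_bases: GAT
  - gene: FLT3
    codon_label: N676
    contig: FLT3_N676
    strand: "+"
    positions: [150, 151, 152]
    ref_bases: AAC
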