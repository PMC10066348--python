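# 17-gene gynecologic cancer predisposition panel with the gene-level
# profile fields the classification engine consumes.
#
# haploinsufficient : gate for PVS1 (loss of function is an established
#                     disease mechanism). Default true for every panel gene;
#                     override per deployment if a gene's VCEP says otherwise.
# z_score           : missense-constraint z (gnomAD style). PP2 fires for
#                     missense variants when z > pp2_z_min. Shipped values are
#                     representative placeholders, not a curated release.
# bs1_cutoff        : per-gene benign allele-frequency cutoff (fraction).
#                     Placeholders in the spirit of calculator-derived
#                     cutoffs; override with curated values for real use.
# homology_masked   : true only for PMS2 — variants outside its unique
#                     (non-pseudogene) region are dropped from classification
#                     and burden.
genes:
  - {symbol: ATM,    transcript: NM_000051.4,    chrom: "11", phenotype: "Breast cancer susceptibility",                                              haploinsufficient: true, z_score: 0.9,  bs1_cutoff: 0.0005, homology_masked: false}
  - {symbol: BARD1,  transcript: NM_000465.4,    chrom: "2",  phenotype: "Breast cancer susceptibility",                                              haploinsufficient: true, z_score: -0.2, bs1_cutoff: 0.0001, homology_masked: false}
  - {symbol: BRCA1,  transcript: NM_007294.4,    chrom: "17", phenotype: "Hereditary breast and ovarian cancer",                                      haploinsufficient: true, z_score: -0.4, bs1_cutoff: 0.0001, homology_masked: false}
  - {symbol: BRCA2,  transcript: NM_000059.4,    chrom: "13", phenotype: "Hereditary breast and ovarian cancer",                                      haploinsufficient: true, z_score: -0.6, bs1_cutoff: 0.0001, homology_masked: false}
  - {symbol: BRIP1,  transcript: NM_032043.3,    chrom: "17", phenotype: "Breast and ovarian cancer susceptibility",                                  haploinsufficient: true, z_score: 0.1,  bs1_cutoff: 0.0001, homology_masked: false}
  - {symbol: CDH1,   transcript: NM_004360.5,    chrom: "16", phenotype: "Breast cancer susceptibility",                                              haploinsufficient: true, z_score: 2.2,  bs1_cutoff: 0.0001, homology_masked: false}
  - {symbol: CHEK2,  transcript: NM_007194.4,    chrom: "22", phenotype: "Breast cancer susceptibility",                                              haploinsufficient: true, z_score: 0.4,  bs1_cutoff: 0.002,  homology_masked: false}
  - {symbol: MLH1,   transcript: NM_000249.4,    chrom: "3",  phenotype: "Lynch syndrome (endometrial and ovarian cancer susceptibility)",            haploinsufficient: true, z_score: 1.6,  bs1_cutoff: 0.0001, homology_masked: false}
  - {symbol: MSH2,   transcript: NM_000251.3,    chrom: "2",  phenotype: "Lynch syndrome (endometrial and ovarian cancer susceptibility)",            haploinsufficient: true, z_score: 1.0,  bs1_cutoff: 0.0001, homology_masked: false}
  - {symbol: MSH6,   transcript: NM_000179.3,    chrom: "2",  phenotype: "Lynch syndrome (endometrial and ovarian cancer susceptibility)",            haploinsufficient: true, z_score: 0.9,  bs1_cutoff: 0.00014, homology_masked: false}
  - {symbol: PALB2,  transcript: NM_024675.4,    chrom: "16", phenotype: "Breast cancer susceptibility",                                              haploinsufficient: true, z_score: -0.4, bs1_cutoff: 0.0001, homology_masked: false}
  - {symbol: PMS2,   transcript: NM_000535.7,    chrom: "7",  phenotype: "Lynch syndrome (endometrial and ovarian cancer susceptibility)",            haploinsufficient: true, z_score: 0.2,  bs1_cutoff: 0.0001, homology_masked: true}
  - {symbol: PTEN,   transcript: NM_001304717.5, chrom: "10", phenotype: "Cowden syndrome (breast and endometrial cancer susceptibility)",            haploinsufficient: true, z_score: 3.8,  bs1_cutoff: 0.0001, homology_masked: false}
  - {symbol: RAD51C, transcript: NM_058216.3,    chrom: "17", phenotype: "Breast and ovarian cancer susceptibility",                                  haploinsufficient: true, z_score: 0.3,  bs1_cutoff: 0.0001, homology_masked: false}
  - {symbol: RAD51D, transcript: NM_002878.4,    chrom: "17", phenotype: "Breast and ovarian cancer susceptibility",                                  haploinsufficient: true, z_score: 0.0,  bs1_cutoff: 0.0001, homology_masked: false}
  - {symbol: STK11,  transcript: NM_000455.5,    chrom: "19", phenotype: "Peutz-Jeghers syndrome (breast, ovarian, and endometrial cancer susceptibility)", haploinsufficient: true, z_score: 2.3, bs1_cutoff: 0.0001, homology_masked: false}
  - {symbol: TP53,   transcript: NM_000546.5,    chrom: "17", phenotype: "Li-Fraumeni syndrome (breast cancer susceptibility)",                       haploinsufficient: true, z_score: 3.6,  bs1_cutoff: 0.0001, homology_masked: false}

# Every cutoff the pipeline uses anywhere; the audit JSON echoes the
# effective values. Strict-inequality semantics are noted per key.
thresholds:
  splice_score_min: 0.5        # splice rescue requires max(ada, rf) > this
  gnomad_het_max: 10           # exclude if gnomAD heterozygotes > this
  local_carrier_max: 20        # exclude if local-cohort carriers > this
  gnomad_hom_max: 3            # exclude if gnomAD homozygotes > this
  local_hom_max: 3             # exclude if local homozygotes > this
  pext_min: 0.5                # biologically relevant transcript: pext > this
  pp2_z_min: 3.09              # PP2 for missense when gene z > this
  ba1_af: 0.05                 # stand-alone benign at af >= this
  pm2_af_max: 2.0e-5           # PM2_SUP at af <= this (or absent from gnomAD)
  ps4_common_af: 1.0e-5        # 0.001%; af >= this uses the case-control branch
  ps4_or_min: 5.0              # PS4 strong in the common branch needs OR > this
  ps4_patients_strong: 4       # rare branch: patients > 4 -> strong
  ps4_patients_moderate: 2     #              patients > 2 -> moderate
  ps4_patients_supporting: 1   #              patients > 1 -> supporting
  bp7_phastcons_max: 0.2       # BP7 for synonymous when phastcons < this
  yates_correction: false      # Pearson chi-square without continuity correction
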