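# Published tally fixtures for the reproduce-printed pathway.
#
# Each fixture stores only integer counts (or rounded percentages that
# determine counts given the stated group size); all statistics are
# recomputed from these counts at run time through the diagnostics module.
# Per-case representative values expanded from the counts are synthetic
# placeholders chosen safely away from every threshold.

afp-combination:
  description: >
    HCC cases with a known serum AFP value, cross-classified by the 20 ng/mL
    AFP-negativity threshold and 5'-assay methylated-copy positivity at the
    10-copy cutoff.
  afp_threshold: 20.0
  msp_cutoff: 10.0
  quadrants:
    afp_neg_msp_neg: 41
    afp_neg_msp_pos: 21
    afp_pos_msp_neg: 29
    afp_pos_msp_pos: 24

msp-positivity:
  description: >
    Sample-level 5'-assay positivity counts by tissue class at the 10-copy
    cutoff (HCC cases vs matched adjacent non-tumour liver).
  msp_cutoff: 10.0
  counts:
    hcc: {positive: 45, total: 120}
    adjacent_non_hcc: {positive: 4, total: 120}

specificity-contrast:
  description: >
    Specificity of the 5'-end vs the 3'-end assay on the same 70 controls
    (hepatitis + cirrhosis); the 2x2 table of control calls is reconstructed
    from the rounded specificities and compared by Fisher's exact test.
  controls: 70
  five_prime_specificity_pct: 97.1
  three_prime_specificity_pct: 60.0
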