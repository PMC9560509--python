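# Printed allele-distribution summaries for E. coli isolate cohorts, as inputs
# for count-table reconstruction. Two kinds of percentage appear in the source
# tables and both are kept in their native form:
#   * group_percentages: share of a GROUP's isolates carrying the allele
#     (environmental vs ExPEC comparison; e.g. 22% of 412 ExPEC -> 91).
#   * allele_percentages: share of an ALLELE's isolates falling in each group
#     (ExPEC-type and phylotype comparisons; rows sum to ~100% of the allele n).
# Reconstructed counts are rounded half away from zero and labelled as
# reconstructions in all outputs.
name: ompa-isolate-cohorts
group_sizes:
  environmental: 78
  ExPEC: 412
  APEC: 171
  UPEC: 148
  NMEC: 80
  AIEC: 13
phylotype_pool:       # dataset trimmed to the four well-populated phylotypes
  A: 45
  B1: 83
  B2: 229
  F: 43
trimmed_environmental: 47   # environmental isolates within the trimmed pool
lump_threshold: 10          # alleles with fewer isolates pooled as "other"
other_n: 40

allele_n:             # allele totals in the trimmed 400-isolate pool
  I_alpha: 57
  I_delta: 96
  II_alpha: 53
  III_alpha: 36      # printed once as n = 14; the running text's 36 is used
  III_gamma: 36
  III_delta: 41
  IV_beta: 23
  IV_delta: 40
discrepancies:
  - "III_alpha n printed as 14 in the summary table but 36 in the text; 36 kept"
  - "listed allele totals (382) plus 40 'other' exceed the trimmed n = 400"

group_percentages:    # percent of group carrying the allele
  I_alpha: {environmental: 29, ExPEC: 9}
  I_delta: {environmental: 3, ExPEC: 22}

allele_percentages:   # percent of allele n found in each group
  I_alpha:   {A: 49, B1: 49, B2: 2, F: 0}
  I_delta:   {NMEC: 53, UPEC: 26, APEC: 6, B2: 100, A: 0, B1: 0, F: 0}
  II_alpha:  {B1: 91, A: 6, B2: 4, F: 0}
  III_alpha: {APEC: 39, NMEC: 4, UPEC: 5, A: 57, B2: 7}
  III_gamma: {AIEC: 46, UPEC: 16, APEC: 0, B2: 100, B1: 0}
  IV_beta:   {F: 96, A: 0, B1: 0, B2: 4}
  IV_delta:  {B2: 100, B1: 0}
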