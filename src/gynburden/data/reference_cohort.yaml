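# Published summary of a national population survey of pathogenic variation
# in the 17-gene gynecologic cancer panel: 7,091 exomes from a population-based
# cohort, with the gnomAD v2.1.1 non-cancer population (N = 134,187) as control.
#
# Per-gene values: distinct P/LP variants, unique heterozygote carriers, and
# the control carrier frequency in percent (null where the survey printed none).
# These printed numbers serve as inputs when reconstructing the burden table;
# control carrier *counts* were not published and are reconstructed from the
# rounded percentages.
n_study: 7091
n_control: 134187
total_carriers: 152
total_distinct_plp: 74
control_total_freq_percent: 2.10
genes:
  ATM:    {n_variants: 18, carriers: 36, control_freq_percent: 0.29}
  BARD1:  {n_variants: 4,  carriers: 4,  control_freq_percent: 0.06}
  BRCA1:  {n_variants: 10, carriers: 28, control_freq_percent: 0.22}
  BRCA2:  {n_variants: 6,  carriers: 18, control_freq_percent: 0.30}
  BRIP1:  {n_variants: 3,  carriers: 3,  control_freq_percent: 0.09}
  CDH1:   {n_variants: 3,  carriers: 3,  control_freq_percent: 0.01}
  CHEK2:  {n_variants: 8,  carriers: 22, control_freq_percent: 0.57}
  MLH1:   {n_variants: 3,  carriers: 3,  control_freq_percent: 0.03}
  MSH2:   {n_variants: 2,  carriers: 2,  control_freq_percent: 0.01}
  MSH6:   {n_variants: 5,  carriers: 5,  control_freq_percent: 0.09}
  PALB2:  {n_variants: 5,  carriers: 9,  control_freq_percent: 0.15}
  PMS2:   {n_variants: 4,  carriers: 10, control_freq_percent: 0.12}
  PTEN:   {n_variants: 0,  carriers: 0,  control_freq_percent: 0.01}
  RAD51C: {n_variants: 3,  carriers: 9,  control_freq_percent: 0.09}
  RAD51D: {n_variants: 0,  carriers: 0,  control_freq_percent: 0.04}
  STK11:  {n_variants: 0,  carriers: 0,  control_freq_percent: null}
  TP53:   {n_variants: 0,  carriers: 0,  control_freq_percent: 0.02}
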