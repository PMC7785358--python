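# Default HFE C282Y / H63D multiplex PCR-RFLP panel.
#
# Enzymes, primer sequences, dye assignments, the FZD1 internal digestion
# control, the FGA/SE33 STR loci and the analytical thresholds describe the
# published assay.  Amplicon lengths, diagnostic-site positions and the STR
# size offsets are self-consistent fixture values (the assay's true genomic
# coordinates are not needed to reproduce its interpretive behaviour); they
# were chosen so that every expected fragment size within a dye channel is
# at least 10 bp from its neighbours.
schema_version: 1
name: hfe_panel
dyes:
  - ATTO 565
  - Yakima Yellow
  - FAM
  - ATTO 550
enzymes:
  - name: SexAI
    recognition: ACCWGGT
    cut_offset: 1
  - name: BspHI
    recognition: TCATGA
    cut_offset: 1
primer_pairs:
  - name: HFE_exon2
    upper_seq: ACATGGTTAAGGCCTGTTGC
    lower_seq: GCCACATCTGGCTTGAAATT
    upper_dye: ATTO 565
    lower_dye: null
  - name: HFE_exon4
    upper_seq: CGGGCCTTGAACTACTACCC
    lower_seq: ACCTCCTCAGGCACTCCTCT
    upper_dye: ATTO 565
    lower_dye: null
  - name: SE33
    upper_seq: AATCTGGGCGACAAGAGTGA
    lower_seq: ACATCTCCCCTACCGCTATA
    upper_dye: Yakima Yellow
    lower_dye: null
  - name: FGA
    upper_seq: GGCTGCAGGGCATAACATTA
    lower_seq: ATTCTATGACTTTGCGCTTCAGGA
    upper_dye: FAM
    lower_dye: null
  - name: FZD1
    upper_seq: CTTGTCCGGCTGTTACACG
    lower_seq: CAGGATGGTGATGGTCTTGAT
    upper_dye: ATTO 550
    lower_dye: ATTO 550
rflp_markers:
  - name: C282Y
    enzyme_name: SexAI
    amplicon_length: 390
    site_position: 247
    variant_creates_site: true
    labeled_end: five_prime
    dye: ATTO 565
    primer_pair: HFE_exon4
  - name: H63D
    enzyme_name: BspHI
    amplicon_length: 208
    site_position: 77
    variant_creates_site: true
    labeled_end: five_prime
    dye: ATTO 565
    primer_pair: HFE_exon2
str_loci:
  - name: FGA
    repeat_unit_length: 4
    size_offset: 120.0
    allele_min: 12.2
    allele_max: 51.2
    stutter_mean: 0.080
    stutter_sd: 0.024
    dye: FAM
    primer_pair: FGA
  - name: SE33
    repeat_unit_length: 4
    size_offset: 180.0
    allele_min: 7.0
    allele_max: 39.2
    stutter_mean: 0.106
    stutter_sd: 0.024
    dye: Yakima Yellow
    primer_pair: SE33
control:
  name: FZD1
  amplicon_length: 309
  sexai_position: 113
  bsphi_position: 161
  expected_double_digest_sizes: [114, 147]
  expected_single_failure_sizes:
    SexAI: 171
    BspHI: 204
  uncut_size: 309
  dye: ATTO 550
  primer_pair: FZD1
thresholds:
  noise_ceiling: 50.0
  cutoff_multiplier: 5.0
  analytical_cutoff: 250.0
  saturation: 32000.0
  stutter_sd_multiplier: 2.0
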