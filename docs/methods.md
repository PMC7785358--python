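# Methods

This note documents the models, conventions and design choices behind
`hfetype`: what exactly is simulated, which constants matter, and what
passing the test suite does and does not demonstrate about the real assay.

## 1. Panel model

The panel (`hfetype/data/hfe_panel.yaml`) is a declarative, validated
description of the multiplex: enzymes, primer pairs with dye labels, RFLP
markers, STR loci, the FZD1 control and the thresholds. Validation is
structural (IUPAC alphabet, cut offset inside the pattern, at least one dye
per primer pair, cross-references resolve) plus one assay-level rule: **no
two expected fragment sizes sharing a dye channel may lie within 1.0 bp**,
the caller's resolution. STR ladder steps within one locus are exempt
(adjacent designations are 1–2 bp apart by nomenclature; identity there is
carried by the designation).

The enzymes, primer sequences, dyes, thresholds, FZD1 double-digest sizes
(114/147 bp), STR allele ranges and stutter parameters describe the
published assay. The quantities the assay description does *not* fix are
chosen once as self-consistent fixture constants and should not be read as
genomic truth:

* *HFE* exon 2 amplicon 208 bp with the BspHI site starting at offset 77
  (labeled cut fragment 78 bp); exon 4 amplicon 390 bp with the SexAI site
  at 247 (cut fragment 248 bp). Chosen so all ATTO 565 sizes
  (78/208/248/390) are ≥ 10 bp apart.
* STR size offsets (fragment size of a hypothetical 0-repeat allele):
  FGA 120 bp, SE33 180 bp. Designation = (size − offset)/4 with the
  remainder as a microvariant decimal; designations are exact by
  construction in simulation.
* Allele ↔ site polarity: the variant allele *creates* the recognition
  site for both markers (`variant_creates_site: true`), by analogy with
  the original RsaI/MboI design; the polarity is config-driven, so a user
  can flip it per marker.

### A size inconsistency, preserved on purpose

The published assay description gives double-digest fragments of
114 + 147 bp on a 309 bp amplicon but single-failure fragments of 171 or
204 bp — which is arithmetically impossible (failure of one cut on a
114 | 48 | 147 layout yields 162 or 195 bp). The panel stores 171/204 for
simulator/caller matching (so the pipeline is internally consistent),
while the sequence-level fixture uses the self-consistent 114 | 48 | 147
layout. The discrepancy is documented here rather than silently resolved;
only the double-digest sizes, which both representations agree on, are
used as headline quantities.

## 2. Digestion engine

Coordinates are 0-based, half-open. A recognition-site *window* may be
discovered on either strand (pattern or its IUPAC reverse complement
matching the top strand); each window yields exactly one cut at
`window_start + cut_offset`. For the palindromic SexAI/BspHI patterns the
bottom-strand scan is a no-op, as it must be. Digestion is complete and
simultaneous (all cuts applied at once); partial digestion is modeled only
as whole-enzyme failure, the scenario the FZD1 control is designed to
catch. Fragments keep the dye of their retained labeled terminus, which is
why FZD1's middle fragment is invisible and one terminal fragment per
enzyme is diagnostic.

Fixture templates are built per marker-allele: primer-flanked random
filler with the diagnostic site placed at the configured offset
(site-absent alleles differ by a single disrupted base), an off-target
repair loop that guarantees **zero** SexAI/BspHI sites anywhere else, and —
on the exon-2 amplicon — a neutral single-base position 12 bp downstream of
the BspHI hexamer standing in for rs1800730 (S65C), demonstrably outside
the recognition site. Filler varies with the seed; fragment sizes never do.

## 3. Signal model

Expected height of a two-copy true-allele peak:

```
E[H] = H_ref · d / d_ref,   H_ref = 8000 RFU at d_ref = 25 ng
```

scaled by allele copy number (heterozygous peaks at half height), with
multiplicative lognormal noise (σ_log = 0.15), hard clipping at the
32 000 RFU saturation ceiling, and uniform ±0.3 bp size jitter. Each FZD1
digest peak runs at relative weight 0.25 — the control is deliberately the
weakest structured signal, which (a) reproduces the observed behaviour
that at 2 ng input the control digest peaks are visible but below the
250 RFU cutoff while everything is comfortably in range at 10–200 ng, and
(b) guarantees that raising the cutoff degrades calls to `no_call` via
control failure before it can ever flip a heterozygote to a false
homozygote. Baseline noise is 8 peaks per dye channel, heights uniform in
(0, 50) RFU, at uniform random sizes in 60–420 bp.

Stutter: every STR allele peak gets one companion exactly one repeat unit
shorter, with ratio drawn from N(mean, SD) truncated at 0 (n−1 stutter
only; n+1 "plus" stutter is not modeled). Components landing at the same
size sum — this is what lets a minor contributor's allele hide inside a
major allele's stutter bin.

Mixtures: a "1 : r" mix gives the minor contributor template share
r/(1+r); per-allele expected heights scale with contributor share and
copy number, shared sizes sum.

What the simulator does **not** emulate: dye pull-up/bleed-through,
size-standard miscalibration, degradation, plus-A artifacts, off-ladder
microvariant discovery, heterozygote imbalance beyond lognormal noise.
Green tests therefore validate the *interpretive rules*, not instrument
physics.

## 4. Caller conventions

* Size matching ±1.0 bp everywhere; height cutoff inclusive (≥).
* Control logic: an enzyme passes iff its double-digest size is present;
  fails iff its failure size or the uncut size appears instead;
  empty control channel ⇒ amplification failure, everything `no_call`.
* A genotype is only emitted when the marker's enzyme control passed —
  the anti-dropout guarantee.
* Stutter filter: a peak one repeat below a taller peak is excluded from
  allele status only while its ratio is `< 0.5`; a comparable-height peak
  there is called as a genuine adjacent allele. The 0.5 ceiling is an
  implementer convention (the assay description defines no heterozygote
  balance or off-ladder policy); without it, adjacent-allele heterozygotes
  would be miscalled as allele + stutter.
* `no_call` reasons are a controlled vocabulary: `control_fail`,
  `amplification_fail`, `no_peaks`.

## 5. Contamination rules

Stutter statistics are estimated from presumed-clean samples: for every
called allele whose stutter bin is not occupied by another called allele,
ratio = stutter-bin height / allele height, with the bin read from the
*unfiltered* table so an empty bin honestly contributes 0. Fewer than two
usable ratios mark a locus's statistics unusable (the stutter rule is then
skipped with a warning).

Per sample, three evidence kinds:

1. **extra_str_allele** — more than two allele-status designations at a
   locus (including off-ladder designations);
2. **elevated_stutter** — a stutter-position peak whose ratio to its
   called parent exceeds mean + 2 SD (the SD multiplier is a panel
   threshold);
3. **extra_rflp_peak** — both cut and uncut peaks present at a marker
   with minor/major height ratio < 0.2. A marker has only two possible
   labeled sizes, so a literal "third peak" cannot exist; the observable
   signature of a contaminating RFLP allele is an apparent heterozygote
   with a grossly imbalanced minor peak, and 0.2 sits far (≈ 7.6 σ of the
   lognormal height ratio) below genuine heterozygote balance.

Any single finding flags the sample by default (`min_evidence=1`,
configurable). With the 2-SD rule, the nominal per-bin false-positive tail
is ≈ 2.3 %; over the 3–4 measurable stutter bins of a typical sample this
compounds to a per-sample rate near 7–8 %, which the tests assert as a
band. The detection-limit experiment uses an adversarial pair — the major
contributor FGA-homozygous (20, 20), the minor carrying allele 19 in its
stutter bin plus clear extra alleles and a foreign H63D allele — and
majority vote over replicates: mixtures are reliably flagged at 1:1 and
1:10 and majority-negative at 1:25 and 1:100.

Identity matching multiplies Hardy–Weinberg genotype frequencies over
shared loci. The bundled frequency table
(`data/str_freqs_synthetic.csv`) is **synthetic** (uniform over common
alleles) and exists to exercise the machinery; real applications must
supply population frequencies, so no population-genetic claim is attached
to the resulting probabilities.

## 6. Problem sizes and determinism

Every simulation accepts an explicit integer seed; cohort members get
sub-seeds from the master generator, and CSV writers use fixed numeric
formatting, so a fixed-seed pipeline is byte-reproducible. The bundled
experiment sizes — 20–100 blanks, a 250-sample characterization cohort
(≈ 500 stutter ratios per locus, SE of the mean ≈ 0.1 percentage point),
100 mixture replicates per ratio, the 60-sample genotype cohort — were
chosen so each estimate's Monte-Carlo error is small against its
acceptance margin while the whole suite runs in seconds.

## 7. Known limitations

* Fragment sizes are idealized (integer bp + jitter); no mobility model.
* One stutter order only; compound-repeat fine structure of SE33 is not
  modeled beyond its single stutter ratio.
* The TaqMan-probe allelic-dropout failure mode that motivates the assay
  is represented only by its *absence* here (S65C never perturbs BspHI
  digestion); the competing assay itself is not simulated.
* Contamination detection probabilities depend on the simulator's height
  model; on real data the detection limit should be re-established from
  instrument-specific stutter statistics.
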