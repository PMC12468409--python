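# Methods

## The classification model

The 2019 EULAR/ACR SLE classification framework is encoded verbatim in
`slemine.catalog`: criterion 1 (ANA) is the entry criterion and carries
no weight; criteria 2–18 are clinical (fever 2, leukopenia 3,
thrombocytopenia 4, autoimmune hemolysis 4, delirium 2, psychosis 3,
seizure 2, non-scarring alopecia 2, oral ulcers 2, subacute
cutaneous/discoid lupus 4, acute cutaneous lupus 6, pleural/pericardial
effusion 5, acute pericarditis 6, joint involvement 6, proteinuria 4,
lupus nephritis class II/V 8, class III/IV 10); criteria 19–22 are
immunologic (antiphospholipid antibodies 2, low C3 *or* C4 3, low C3
*and* C4 4, anti-dsDNA/anti-Smith 6). The weighted sum across all
positive non-entry criteria totals at most 88.

A patient is classified

* **SLE−** iff the entry criterion is not positive;
* **SLE+** iff entry passes, at least one clinical criterion (2–18) is
  positive, and the plain weighted sum is ≥ 10;
* **UCTD** otherwise (entry passed, later gates unmet).

Two points here are deliberate package-level choices. First, the
framework itself never spells out the "entered but unmet → UCTD"
mapping; the tripartite outcome implies it, and we implement it
explicitly. Second, scoring is the *plain weighted sum*, not the
official per-organ-domain maximum; the official behaviour is available
via `classify(..., domain_max=True)` with the standard ten-domain
partition, but the plain sum is the default because every other
statistic in the package is built around it. `not_reported`
determinations score as negative: a criterion absent from the record
contributes nothing. `first_to_ten` mode evaluates criteria in
descending weight order (ties by ascending id) and stops at 10 points
once a clinical criterion is present; since the sum is monotone in the
visited prefix, the class always equals the exhaustive result
(property-tested), only the attrition bookkeeping differs.

## Synthetic cohort generator

`slemine.synthetic` emulates the structure of a private 78-patient
record cohort rather than any real data:

* **Cohort frame.** 78 patients, exactly 39 with records ending at
  clinical classification (pre_SC) and 39 beginning after a prior
  classification (post_SC), allocated by largest remainder and
  shuffled. Classes are sampled per patient with probabilities
  48/78 SLE+, 9/78 UCTD, 21/78 SLE−.
* **Latent criterion truth.** Per-criterion positivity is sampled
  conditionally on class. Where per-class positive counts were
  published for this framework we use them as anchors (per 48 SLE+ /
  9 UCTD: leukopenia 19/1, alopecia 10/5, oral ulcers 19/4, joint
  involvement 40/8, proteinuria 9/5, low C3/C4 14/0, anti-dsDNA 23/0);
  all other criteria default to 0.15 (SLE+), 0.10 (UCTD), 0.05 (SLE−).
  These defaults are assumptions — no per-criterion clinical prevalence
  table exists for the cohort being emulated. Sampled statuses are then
  minimally repaired so the latent class is *consistent with the
  classification rule*: SLE+ forces ANA positive, one clinical
  criterion (joint involvement if none), and flips criteria on in
  decreasing prevalence order until 10 points; UCTD forces ANA positive
  and sheds heaviest positives while still SLE+; SLE− forces ANA
  negative. The graded pairs (nephritis II/V vs III/IV; one vs both
  complement components low) are kept mutually exclusive so plain
  additive scoring never double-counts a finding.
* **Evidence rendering.** Each (patient, criterion) draws an evidence
  style — numerical 0.45, phrase 0.30, descriptive 0.10, not_reported
  0.15 by default — and renders a sentence from per-criterion template
  banks (e.g. "ANA titer 1:160 on immunofluorescence.", "Positive ANA
  result documented.", "Speckled ANA pattern noted."). Numerical
  positives/negatives embed values on the correct side of clinically
  sensible thresholds (ANA titer ≥ 1:80, WBC < 4.0 ×10⁹/L, platelets
  < 100, haptoglobin < 30 mg/dL, urine protein > 500 mg/24 h,
  anticardiolipin IgG > 40 GPL, C3 < 90 mg/dL, anti-dsDNA > 30 IU/mL,
  temperature ≥ 38.3 °C). Descriptive renderings exist only for
  positive findings; criteria without a natural quantitative rendering
  fall back to phrase style. Snippets are placed in one of 3–5 dated
  notes inside the record window `[anchor − window_days, anchor]`
  (anchor fixed at 2024-06-30, window 540 days ≈ the 1–2-year histories
  being emulated), interleaved with Poisson(2) criterion-irrelevant
  distractor sentences per note.
* **Record degradation.** `out_of_window_prob` (reference value 14/57)
  makes a truth-positive patient's ANA evidence predate the window: by
  default the snippet is simply omitted (the record never contained the
  old test); with `retain_dated_history` it is instead written into a
  pre-window history note, which exercises date-based window filtering
  in the extractor. `low_titer_trap_prob` (reference value 5/21) makes
  a truth-negative ANA record assert positivity at a 1:40 titer.
  `not_reported` styles leave a true finding out of the record
  entirely. Clinical determinations are sparsified to a 15-patient
  fully-determined subset (drawn from pre_SC) in the reference config;
  ANA stays determined for everyone.
* **Determinism.** All randomness flows from one
  `numpy.random.default_rng(seed)`; a config reproduces a
  byte-identical cohort.

What the generator does **not** model: OCR noise, demographic
structure, longitudinal disease evolution, inter-note coreference,
free-text beyond one-sentence findings, or criteria whose evidence
spans multiple documents. Passing tests therefore demonstrate that the
pipeline's logic is correct *under these mechanisms*, not that any
particular accuracy level transfers to real records.

## Extraction

The extractor is a deterministic lexicon/rule engine, written as a
stand-in with the same interface contract a generative-model reader
would have (and engineered against the generator's template banks; its
keyword lists are original to this package).

* **First pass (permissive).** Every case-insensitive, word-bounded
  keyword/keyphrase hit and every quantitative-pattern match in any
  note becomes a mention with character span, containing sentence,
  kind (numerical / phrase / descriptive) and parsed value. ANA
  matching is maximally permissive: any titer, pattern or test mention
  is harvested regardless of value. Out-of-window mentions are flagged,
  not dropped.
* **Second pass (stringent).** Per criterion: if `enforce_window` is
  on, pre-window mentions are excluded. Quantitative mentions outrank
  phrasing; among them the latest-dated result decides, positive if it
  satisfies the criterion's threshold (ties at a date resolve
  positive). ANA uses the ruleset's titer threshold (default 1:80), so
  a 1:40 "positive" assertion is scored insufficient. Otherwise phrase
  and descriptive mentions decide: polarity comes from negation cues in
  the containing sentence (sentence = maximal span between terminal
  punctuation — a deliberately simple contextualization window);
  positives dominate, and an uncorroborated positivity phrase counts
  only while `accept_uncorroborated_phrase` is on (default on — the
  permissive behaviour that produces phrase-only false positives). No
  surviving mention ⇒ `not_reported`; only negative evidence ⇒
  negative.
* **Replicates and consensus.** Extraction runs in k = 5 replicates;
  replicate r drops each non-core lexicon key with probability
  `perturbation` under a generator seeded from (seed, r). Consensus is
  the majority on the positive vs not-positive contrast; agreement of
  5/4/3 replicates maps to consistency 1.0/0.6/0.2 (total: five binary
  calls always agree at least 3–2). When the not-positive side wins,
  the reported label is the modal specific label among those calls,
  ties resolved to negative; for even k (non-default) ties on the
  binary contrast resolve positive. Both tie-breaks exist only for
  determinism and are exercised by tests.

## Evaluation statistics

* **Confusion and accuracy.** Patients clinically `unspecified` for a
  criterion are excluded from that criterion's matrix; `not_reported`
  predictions count as predicted negatives. Sensitivity, specificity,
  PPV and NPV are reported with "n/a" when a denominator is zero;
  rounding (2 d.p.) happens only at rendering. The pooled row
  micro-averages summed cells; a macro-average is emitted alongside
  because pooled-row conventions vary across reports.
* **Wilson intervals.** 95% score intervals attach to each metric's own
  numerator/denominator; the implementation is the closed form
  (vectorized, boundary endpoints exact), cross-checked in tests
  against statsmodels and covering 93–97% empirically at the sample
  sizes in play.
* **Fisher exact.** Two-sided via scipy (sum of hypergeometric
  probabilities ≤ observed), verified exactly against rational
  enumeration for all tables with n ≤ 12. Class-difference tests use
  the 2×2 of criterion-positive counts against class totals (48 SLE+,
  9 UCTD) — the construction is stated because published p-value
  thresholds for such comparisons are not reproducible without it, and
  for the anti-dsDNA counts the exact two-sided p is 0.0078.
* **Weighted influence.** For class K, criterion i with Nᵢ positive
  determinations among clinical-class-K patients and weight Wᵢ has
  influence NᵢWᵢ / Σⱼ NⱼWⱼ over criteria with nonzero counts, so
  influences sum to 1 per class; zero-count criteria report 0 and stay
  out of the denominator. Only influence *ratios* are comparable with
  influence values published on other normalizations. The attached
  interval is the Wilson interval on the count share Nᵢ/ΣN rescaled by
  the weight factor — an approximation, labelled as such in output,
  since no exact construction exists for a ratio of dependent sums.
* **Concordance.** 3×3 clinical-vs-predicted contingency (SLE−, UCTD,
  SLE+ order), exact-match fraction = trace/n, and per-class partition
  fractions for both labelings.

## Numerical and scale choices

Large-sample checks (class-mix conservation, missingness transfer) run
at n = 2000 patients with k = 1 replicate — chosen so binomial
tolerances are tight (4σ ≈ 0.04 on a 0.2 rate) while the whole suite
stays interactive; the evidence-style check uses n = 5000 (generation
only). The perfect-world recovery check runs the full 5-replicate
pipeline on the 78-patient reference frame with every degradation
mechanism off and requires exact ground-truth recovery, which the
template/lexicon collision-matrix test (every rendered template scores
correctly for its own criterion and triggers no other) makes robust
rather than incidental.

## Known limitations

* The extractor's negation handling is a single-sentence cue list; it
  will mis-scope clause-level negation ("no fever but recurrent oral
  ulcers" scores both criteria from the same sentence — the first
  correctly negative, the second incorrectly negative).
* The default lexicon is calibrated to the synthetic template banks;
  applying it to real notes requires supplying a lexicon YAML and
  should be expected to need iteration.
* Influence intervals are approximate (above); treat them as
  indicative spread, not exact coverage.
* The generator's per-criterion prevalence defaults for unanchored
  criteria are flat assumptions; cohort-level statistics that depend on
  them (e.g. attrition branch counts) are emulation-shaped, not
  reproductions.
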