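# Methods

## The scoring model

`pullcall` treats an AP-MS pulldown as a mixture of two protein
populations: a large background of nonspecific binders and a small set of
proteins genuinely in complex with the bait. The observable is the
spectral (peptide) count — a semi-quantitative abundance proxy that grows
with both protein abundance and protein length, and varies with pulldown
efficiency between replicates. The normalization chain removes both
nuisance factors:

    r(p, a) = ( c(p, a) / L(p) ) / ( c(b, a) / L(b) )

so `r` is a length-corrected, bait-relative abundance, comparable across
assays. All non-bait, non-zero cells are pooled across assays as
independent observations on the log2 scale and modelled as

    x ~ w_bg N(m_bg, v_bg) + w_hi N(m_hi, v_hi),   m_bg < m_hi.

The component with the larger mean is the bound population ("higher
peptide counts" after normalization); a protein's interaction score is the
posterior probability of that component evaluated at the protein's mean
log2 value across the assays in which it was observed. The final call
requires `posterior > 0.5` (strict) and a summed raw count of at least 5 —
the count floor suppresses proteins whose high ratio rests on one or two
spectra.

### Modelling decisions that were genuinely open

- **One posterior per protein.** The mixture is trained on pooled
  per-assay observations, but each protein needs a single score. We
  evaluate the posterior at the protein's arithmetic mean log2 value
  (proteins seen in fewer assays contribute only those assays; nothing is
  imputed). The alternative — multiplying per-assay posteriors — sharpens
  scores for reproducibly seen proteins but punishes single-dropout
  interactors severely, so it is not the default.
- **Count floor applies to the summed counts.** Classification happens
  after merging, so "at least five" is read against the per-protein total
  across assays. `count_mode="any_assay"` instead requires a single assay
  to reach the floor on its own.
- **Zero cells are excluded, not pseudocounted.** log2(0) is undefined;
  rather than invent a pseudocount scale we drop zero cells from training
  and record each exclusion. A `pseudocount` option (added to raw counts
  before length normalization) exists for users who prefer to keep
  dropout cells, default 0.
- **The bait is excluded from training.** Its log2 value is identically 0
  by construction and would otherwise act as a fixed outlier; it is
  reported in the output flagged as bait with sentinel posterior 1.
- **One mixture per condition.** Replicates of one bait in one growth
  condition share a fit; conditions are scored independently rather than
  jointly, since nothing ties their background shapes together.

## The EM engine

The mixture is fitted by expectation–maximization with responsibilities
computed in log space (`logsumexp`), a variance floor of 1e-6 log2² units
against single-point collapse, and convergence on the absolute change in
total log-likelihood (tol 1e-8). `max_iter` defaults to 10000: near-merged
optima are approached along likelihood ridges where EM moves slowly, and a
1-D iteration is O(nk), so a generous cap is cheap. Fits are reported in
canonical ascending-means form with the seed recorded.

Initialization runs `n_restarts + 1` EM runs and keeps the highest
likelihood:

- restart 0: deterministic quantile start — component j at the
  (2j+1)/(2k) sample quantile;
- restart 1: deterministic upper-tail start with the last component at the
  98th percentile — pulldown data are expected to carry a minority
  high-abundance component, and a bulk-quantile start can miss it;
- remaining restarts: distance-weighted (k-means++-style) seeding from the
  data with a seeded generator.

Every start is then moment-matched: points are hard-assigned to the
nearest seed mean and each component takes its cluster's weight, mean and
variance. This matters: starting a component inside a small distant
cluster with the *pooled* variance lets the first E-step dissolve it into
the bulk, and the run converges to a merged local optimum with visibly
lower likelihood.

Model-order selection is available via BIC
(`(3k − 1) ln n − 2 log L`, `select_k`), but the default is fixed k = 2:
the question the classifier answers is binary.

## The synthetic-data generator

`simulate()` emulates the structure the scoring chain assumes: one bait
present in every assay (negative-binomial counts around mean 400, clamped
≥ 1), 10 interactors with latent bait-relative log2 abundances from
N(−2, 0.8), 300 background proteins from N(−7, 1.2), lengths uniform on
100–3000 aa, three assays. Expected counts are constructed so that the
pipeline's own normalization chain recovers the latent log2 value in
expectation; observed counts are negative-binomial (size 5 — spectral
counts are overdispersed, and the pipeline should be robust to it even
though the mixture assumes Gaussian log2 values), and background cells
drop out with probability 0.15 per assay. Interactors never drop out,
mirroring the reproducible detection of genuine complex partners across
replicates. All draws flow from one seed; identical seeds give
byte-identical tables.

What the generator does *not* emulate: peptide-level identification error,
shared/razor peptide ambiguity, control pulldowns, and correlated
efficiency drift across proteins within an assay. Passing tests therefore
demonstrate correctness of the scoring machinery under the stated
two-population model, not robustness to every artefact of real MS data.

### Integer censoring and what "recovery" means

At background abundance 2⁻⁷ relative to a bait of ~400 counts, expected
background counts are of order 1–3 — and lower still when the bait protein
is long, which shrinks every expected prey count via the length ratio.
Cells that draw 0 are unusable on the log scale, and the cells that
survive are biased upward (a count of 1 where 0.3 was expected reads as a
high ratio). In replicates where this censoring is strong, the *true*
maximum-likelihood two-component fit places its high component between
the censored background tail and the interactor cluster — verified by
initializing EM at the generating parameters and watching it move away.
Parameter recovery is therefore asserted on the **median over ten seeded
replicates** (median fitted high-component mean within ±0.5 log2 units of
the generating interactor mean), matching how the engine-level recovery
check is aggregated. Classification is much less sensitive than the
component means: sensitivity and specificity stay high even in
heavily-censored replicates, because interactors remain far from the bulk
of the background.

## Tabular formats

All tables are tab-separated UTF-8 with a header. Count tables come in
three explicit dialects (`long`, `wide`, `peptide` — the last is summed
per protein before validation); there is no format sniffing, because MS
exports vary and silent guessing hides errors. Protein IDs are
case-sensitive and whitespace-trimmed. A reader for MaxQuant
proteinGroups-style exports (`Peptides <experiment>` columns) is provided
but never chosen automatically. Zeros are retained at read time —
excluding them is a scoring-stage decision. Duplicated (protein, assay)
rows, negative or fractional counts, non-positive or conflicting lengths,
and a bait absent from any assay are all hard errors.

## The transcript phase sorter

`phase_sort` retains transcripts with |log2 fold change| strictly greater
than 1.5 and (by default) adjusted P ≤ 0.1, then partitions them by
annotated cell-cycle peak phase (G1, S/M/C, noncyclical). Rows with
missing adjusted P fail the filter when the cutoff is active — the usual
treatment of independent-filtering NAs in differential-expression output.
Unannotated transcripts fall into the noncyclical group with a logged
warning, so the three groups always partition the retained set.

## Numerical notes and limitations

- Posteriors are computed in log space and match direct Bayes evaluation
  to better than 1e-10 over the support of the fit; far outside the
  support a plain-density evaluation underflows while the log-space path
  stays exact.
- Ties in `select_high_component` (equal means) go to the heavier
  component, then the lower index.
- `classify` is monotone in both thresholds: raising either never turns a
  negative verdict positive.
- The per-protein posterior uses the mean of log2 values, not the
  posterior of the mean count; with ≤ 3 assays the difference is small but
  nonzero.
- With no control pulldowns, sticky abundant background proteins that
  track the bait's abundance can still score highly; CRAPome-style
  filtering or SAINT/CompPASS scoring are deliberately out of scope.
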