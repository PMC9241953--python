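# pullcall

Score prey proteins from affinity-purification mass-spectrometry (AP-MS)
pulldowns: given replicate assays of a tagged bait, decide which
co-purifying proteins are genuinely in complex with it.

AP-MS experiments recover the bait together with a long tail of nonspecific
background. `pullcall` separates the two populations from spectral counts
alone, with no control pulldowns, using a normalization chain and a
one-dimensional Gaussian mixture. It was built around kinase-pulldown
studies in *Toxoplasma gondii* (bait-style IDs like `TGME49_267580`), but
nothing in it is organism-specific.

## Method

For each protein *p* and assay *a* with summed peptide/spectral count
*c(p,a)* and protein length *L(p)* (amino acids), with bait *b*:

1. **Length normalization** — `v(p,a) = c(p,a) / L(p)` (longer proteins
   yield more detectable peptides).
2. **Bait normalization** — `r(p,a) = v(p,a) / v(b,a)`, making assays of
   different pulldown efficiency comparable; the bait maps to 1.
3. **Merge and log2** — all non-bait, non-zero `r(p,a)` across assays are
   pooled as independent observations `x = log2 r(p,a)`.
4. **Mixture model** — the pooled values are fitted with a k = 2 Gaussian
   mixture `Σ_j w_j N(x; m_j, v_j)` by expectation–maximization; the
   component with the larger mean is the *bound* population.
5. **Classification** — each protein is scored by the bound-component
   posterior at its mean log2 value and called an interactor when
   `posterior > 0.5` (strict) **and** its summed raw count is ≥ 5.

A synthetic-data module generates complete pulldown studies (negative-
binomial counts, background dropout, ground-truth labels) so the entire
chain is testable without any raw MS data, and a small utility sorts
differentially expressed transcripts into cell-cycle peak-phase groups
(|log2 fold change| > 1.5, adjusted P ≤ 0.1).

## Worked example

`examples/score_synthetic_pulldown.py` simulates three replicate pulldowns
(1 bait + 10 interactors + 300 background proteins) and scores them:

```
simulated 311 proteins x 3 assays
799 pooled log2 observations (134 cells excluded: bait rows and zero counts)
mixture: background mean -7.22, bound-component mean -2.04 (weight 0.033)
10 proteins called in complex (posterior > 0.5 and summed counts >= 5):
  PREY_0001  posterior=0.992  log2(bait-rel)=-1.44  counts=13184
  ...
vs ground truth: sensitivity 1.00, specificity 1.000, 0 false discoveries
```

The fitted bound component sits at −2.04 log2 units relative to the bait —
the generator placed true interactors at −2.0 — and its weight (0.033)
matches the interactor fraction of the pooled observations. All 10 planted
interactors are recovered with no false discoveries.

The other examples show the mixture engine on its own
(`examples/fit_mixture.py`) and the transcript phase sorter
(`examples/phase_sort_transcripts.py`).

## Command line

```sh
pullcall simulate --seed 1 --out-dir sim_out
pullcall score --counts sim_out/counts_long.tsv --lengths sim_out/lengths.tsv \
    --bait BAIT --out-dir run_out
pullcall phase-sort --de de.tsv --annotation phases.tsv
pullcall replay run_out/run_record.json --out-dir run_out_replayed
```

`score` writes a ranked calls table, a fit summary, an exclusion log and a
JSON run record; `replay` reproduces a run byte-for-byte from the record.

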