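# Methods

## Sequence model and feature extraction

Sequences are normalized to RNA on input (T→U, uppercased); records with
ambiguity codes are rejected outright rather than window-skipped, so every
downstream count has an unambiguous denominator. The hard length floor is
M ≥ 5 — the shortest sequence for which all three reading frames contain a
full triplet — while ≥ 200 nt is the recommended (not enforced) threshold
for genuine lncRNAs.

The 257-feature layout is: 64 overlapping 3-mer frequencies, 3 × 64
reading-frame triplet frequencies, one MFE scalar. Both k-mer and
reading-frame blocks are *frequencies*, not counts, so sequences of
different lengths are comparable; each reading-frame block is normalized by
its own triplet count so the three frames sit on a common scale. The MFE is
used raw (kcal/mol) by default; an `mfe_per_nt` option divides by length
for users who prefer a size-free stability measure. Feature order is fixed
(triplets lexicographic with A<C<G<U, frames 1–3 in order, MFE last) and
recorded in a manifest.

Redundancy reduction is a greedy incremental clustering: sequences are
visited longest-first, each joining the first representative sharing at
least the identity threshold (default 0.80) of the shorter sequence's
distinct 5-mers. This reproduces the *shape* of a CD-HIT-style redundancy
step with a transparent, deterministic rule; it is not CD-HIT, and no
parity with it is claimed. Word size 5 and word-containment similarity are
this package's choices; the threshold is global on the shorter sequence's
vocabulary.

## Secondary structure

The built-in folder minimizes a loop-decomposition energy over all
pseudoknot-free structures with pairs in {AU, UA, CG, GC, GU, UG} and
hairpin loops of at least 3 nt. The energy model is deliberately simple:

| term | value (kcal/mol) |
| --- | --- |
| stack of two G:C-type pairs | −3 |
| stack involving an A:U-type pair | −2 |
| stack involving a wobble pair | −1 |
| hairpin loop (size ≥ 3) | +3 |
| bulge/interior loop of size s | +2 + 0.5·s |
| multibranch loop with b branches | +4 + 1·b |

Half-integer values keep exhaustive-enumeration oracles exact; these are
*not* the Turner parameters, and the folder exists to make the pipeline
self-contained and exactly testable (the dynamic program provably returns
the global minimum of the same scoring function the tests enumerate).
Interior/bulge loops larger than 30 nt are not searched — the standard
restriction, which cannot bind on the short sequences where optimality is
verified. For biological fidelity the external RNAfold program is the
recommended MFE backend and is used automatically by the pipeline when
present; its dot-bracket output can also be imported from a file.

Substructure windows follow a three-character rule: `...` is loop,
`(((`/`)))` is stem, anything mixed is junction — the mixed case covers
`..(`, `).. `, `(.)` and all other boundary windows. Triplex-by-substructure
tables are conditional distributions: freq(t | category) in percent, each
category column summing to 100, so the uniform "random combination"
baseline is 100/64 = 1.5625% (printed half-up as 1.563%). A category with
zero windows is reported as an all-zero column plus an explicit flag rather
than NaNs.

## Class balancing

Borderline-SMOTE (type 1) restricts interpolation seeds to the DANGER set —
minority samples whose m nearest neighbours (default m = 5, over the whole
dataset) are at least half, but not all, from other classes — and falls
back to classic SMOTE over the whole minority class when no sample is
borderline (logged, not silent). ADASYN allocates the deficit
proportionally to per-sample difficulty r_i (fraction of other-class
neighbours), rounding with residue assigned to the hardest samples. Both
record parents and the interpolation coefficient u, so the segment identity
x = parent_i + u·(parent_zi − parent_i) is exact and auditable, and a
convex combination of per-block-normalized parents remains normalized.

Synthetic points then pass an uncertainty filter: 25 depth-3 trees trained
on bootstrap resamples of the *real* data vote on each synthetic point;
points with vote entropy above τ = 0.75·ln k nats, or whose majority vote
contradicts their assigned class, are discarded. This entropy-screening of
synthetic samples is this package's concrete interpretation of
uncertainty-weighted filtering; it is conservative in that it can only
remove synthetic points, never real ones. Outlier removal is per-class:
samples farther than mean + 3·sd of centroid distances are dropped, then
near-duplicates (within 1e-9) are collapsed. Euclidean distances are
computed after standardizing the MFE column, whose kcal/mol scale would
otherwise dominate the frequency features.

The default balancing plan raises each minority class toward the
second-largest class count, capped at 20× the class's original size so a
handful of real points is never asked to span hundreds of synthetic ones.

## The boosting model

The round coefficient α_t = ½·ln((1−ε_t)/ε_t) + ln(k−1) (natural log)
keeps the classic binary ½-factor and adds the multiclass offset; at k = 2
it *is* classic AdaBoost, and the test suite asserts exact α-sequence and
prediction equality against an independent transcription of the binary
update. Weight updates multiply by e^(∓α_t) and renormalize to sum to 1.

Because of the retained ½-factor, α_t > 0 whenever
ε_t < (k−1)²/((k−1)²+1) — about 0.941 for k = 5 — which is far *weaker*
than the usual multiclass requirement that the base learner beat 1 − 1/k.
The implementation enforces the coefficient's own positivity boundary
(stop when α_t ≤ 0; error if the first round already fails it) rather than
a separate 1/k accuracy check, since the boundary is what the formula
actually implies.

Numerical choices: weighted error is clamped to [1e-10, 1−1e-10] so a
perfectly fitting round yields a large finite α; training also stops after
such a round, since every weight would otherwise be rescaled identically.
The base learner is a depth-limited decision tree (default depth 2) fitted
with the current sample weights; a fixed random state makes training
deterministic given data order. Prediction is the α-weighted vote with
ties broken toward the earlier class in the sorted class set; normalized
per-class scores (votes divided by Σα) feed the ROC curves. Models
serialize to JSON as nested split records and reload to bit-identical
predictions.

## Evaluation

Multiclass reports give per-class one-vs-rest TP/FN/FP/TN, Sn, Sp, and MCC
plus the single overall accuracy trace/total. (A well-known printed variant
of the accuracy formula, (TP+FN)/total, is the positive-class prevalence,
not accuracy; the standard definition is used.) MCC is defined as 0 when
its denominator vanishes. AUC is the tie-corrected trapezoidal /
Mann-Whitney area, per class one-vs-rest, macro-averaged over classes that
have both positives and negatives.

Cross-validation is stratified; the fold count is reduced to the smallest
class size when necessary (the 5-class benchmark, with its size-8 minority,
runs as 8 folds when 10 are requested). Oversampling happens strictly
inside each training fold — per-fold targets are rescaled by (folds−1)/folds
— so synthetic points can never reach a test fold; pooled predictions cover
each real sample exactly once. This in-fold protocol is stricter than
balancing before splitting, and accuracies under it are not directly
comparable with pipelines that balance first.

The F-score of feature i is the ratio of between-class scatter of the class
means to the pooled within-class variance (each class needs ≥ 2 samples);
it is invariant to affine rescaling of a feature. A 1e-12 guard applies
only when all within-class variances vanish. Ranking ties break by feature
index.

## Synthetic benchmark

The generator draws sequences triplet-wise from a 64-triplet distribution:
background base probabilities multiplied per triplet, enriched triplets
scaled by ρ and renormalized; lengths are uniform in the configured range
rounded to triplets plus a 0–2 nt tail. Planting at triplet granularity
puts the full signal into overlapping 3-mers and frame-1 features while
frames 2 and 3 see only attenuated, phase-shifted echoes — so feature
ranking can legitimately prefer one frame over another for the same
triplet.

The standard benchmark has 5 classes of (200, 120, 45, 30, 8) sequences,
200–600 nt, each enriched ρ = 6 in two class-specific triplets. The 25:1
majority:minority ratio exercises the imbalance regime of real localization
datasets (which reach beyond 40:1) at a size that keeps the full pipeline —
folding, in-fold balancing, 80 boosting rounds, 8-fold CV — in the
low-minutes range on one CPU; these are the problem sizes the acceptance
script uses. Passing on this benchmark demonstrates that the machinery
recovers planted compositional signal under heavy imbalance; it says
nothing about accuracy on real lncRNAs, whose localization signal is
weaker, structured, and confounded.

## Known limitations

- The built-in energy model is a caricature; MFE features for real analyses
  should come from RNAfold.
- The redundancy filter is not CD-HIT and will split/merge borderline
  clusters differently.
- Single-localization labels only; multi-compartment lncRNAs are out of
  scope.
- Minority-class gains from oversampling are seed-sensitive at n = 8: with
  so few held-out positives, sensitivity moves in steps of 1/8, and some
  seeds show ties rather than strict improvement.
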