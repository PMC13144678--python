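# Methods

## Problem setting and data model

A promoter is modelled as the 400 bp immediately upstream of a gene's start
codon on the coding strand. Extraction from a genome FASTA + GFF3 keeps a
gene only if that window, extended a further 100 bp upstream, contains no
other annotated gene body, and if the window itself lies inside the contig
(no padding is fabricated at contig edges). GFF coordinates are 1-based
inclusive; every internal offset is 0-based half-open. The "≥100 bp
separation from the nearest neighbouring gene" rule is implemented as
gene-body overlap against the margin-extended window; measuring from the
promoter's distal end is an assumption — the separation could equally be
anchored elsewhere, and the chosen rule was picked as the simplest auditable
interval test. Ambiguous bases (N) are retained and tokenized distinctly;
promoters above 10 % N are dropped (configurable).

Corpus splitting is by species holdout: the holdout species' promoters form
the test set, a seeded without-replacement sample of the remainder forms the
validation set, the rest trains. The three sets partition the input exactly.

## Synthetic corpus generator

`generate_synthetic_corpus` emulates the statistical skeleton of a promoter
corpus: i.i.d. bases at a configurable GC fraction (default 0.5; symmetric
within GC and AT), optional planted core elements, and 64 bp of extra 5'
context per promoter so length-compensating sample generation works exactly
as it does for genome-extracted corpora. With `plant_elements`, each
promoter receives a TATAWAW motif (W ∈ {A, T}) at a seeded position in the
distal-to-mid region (offsets L/10 to 0.6·L) and a TSS 40–120 bp downstream,
both recorded in the promoter record; these spacings are ordinary for yeast
core promoters and give the element-disruption filter something real to hit.

What the generator deliberately does **not** reproduce: dinucleotide and
higher-order composition, nucleosome-positioning signals, real TFBS content,
homology between promoters, and inter-species divergence. Tests passing on
synthetic corpora therefore demonstrate the machinery (shapes, conservation
laws, determinism, trainability, calibration against chance), not biological
predictive power; the latter requires full-scale training on real promoter
corpora, which is out of scope for the desk-scale presets.

## Training-sample construction

For one sample with rewriting length m (MSRL ∈ {5, 40}):

1. q ~ Uniform{8..64}; a query start is drawn uniformly (excluding, when
   m > q, the m − q most distal starts, so later trimming cannot eat into
   the rewrite window); the query is sliced from the base promoter.
2. The query's slot is overwritten with an m-length segment cut at a uniform
   offset of the auxiliary promoter. The sequence length changes by m − q.
3. Length bookkeeping anchors the 3' (start-codon-proximal) end: when the
   sequence shrank, the missing q − m distal bases are prepended from the
   promoter's recorded 5' context, falling back to seeded background bases
   drawn from the promoter's own composition when no context exists; when it
   grew, the excess is trimmed from the 5' end. Anchoring the 3' end keeps
   TSS-proximal coordinates fixed; the alternative (anchor 5', shift the
   proximal end) would move exactly the biology the model is supposed to
   learn.
4. 2–3 decoy windows of length m, mutually disjoint and disjoint from the
   rewrite window, are overwritten in place with auxiliary segments (uniform
   positions, up to 100 placement retries before a hard error).
5. The label is the indicator of the rewrite window; its OQPR bin is
   1 + ⌊midpoint/40⌋, bin 1 being the most distal 40 bp.

The stream draws base promoters uniformly over all promoters of species with
≥2 members (single-promoter species are skipped with a logged warning) and
the auxiliary uniformly among the base's same-species partners. Query
lengths and positions are uniform by construction; the suite checks the
length distribution by a χ² goodness-of-fit test at α = 0.01 over 10⁴
samples. The query length range is 8–64 by default and configurable
(16–64 appears in some descriptions of the same procedure; the wider range
is the default here).

## Place-back model

Topology (per the two-branch design): promoter branch — embedding (6 tokens:
ACGTN + query pad) with fixed sinusoidal positional encoding, `n_conv_blocks`
stride-2 convolutions (400 → 400/2ⁿ positions), a transformer encoder stack,
then per block nearest-neighbour ×2 upsampling + convolution back to 400
positions, and a linear projection to the fusion space. Query branch —
embedding (pad positions zeroed) → single-layer bidirectional LSTM → linear
projection. Fusion — scaled dot products between all (promoter position,
query position) pairs, padded query slots masked to −∞, max over the query
axis, then a learned scalar affine and a sigmoid.

Choices made where the design was open:

- **Loss**: mean per-position binary cross-entropy — the natural likelihood
  for independent sigmoid outputs against a binary mask.
- **Positional encoding**: sinusoidal (parameter-free) added to embeddings.
- **Max pooling axis**: over the query axis of the attention product; this is
  the only reduction that leaves a 400-aligned output.
- **Query padding**: to 64 with an explicit mask, for batchability.
- **Thresholding**: precision/recall binarize at p ≥ 0.5 (configurable);
  precision is macro-averaged over samples that have at least one positive,
  recall (hits/MSRL) over all samples. Macro averaging is the implemented
  reading of "average precision" here.

Presets: `paper_scale` (~5.5 M trainable parameters: embedding 192, channels
256, 4 transformer layers of 8 heads, FFN 1024, LSTM hidden 256) matches the
multi-million-parameter regime of a full training run and is built, counted
and checked, but never trained in the suite; `test_scale` (~33 K parameters:
embedding 16, channels 32, 1 transformer layer, LSTM hidden 16) keeps every
training path CPU-testable. Optimisation is Adam (lr 3 × 10⁻³ for the desk
presets); all initialisation flows from one `numpy.random.Generator` seed, so
builds and training traces are bitwise reproducible on one machine.

The networks run on a small reverse-mode autodiff core written on numpy
(float32), implementing exactly the operations these models need —
broadcasting arithmetic, batched matmul, strided 1-D convolution via
im2col, embedding scatter/gather, max/mean reductions, layer norm, softmax,
and fused numerically-stable BCE/cross-entropy losses. Gradients are
verified against central finite differences in the test suite. Ties in max
reductions route the gradient to the first argmax — a deterministic
tie-break.

## Determiner and consensus

Each determiner reads the raw 4 × 400 stack (rows ordered 5, 5, 40, 40; no
normalisation — the curves are already probabilities) and carries two
softmax heads: rewrite length (2 classes) and OQPR (10 classes). CNN
variants apply strided convolutions and flatten; LSTM variants average-pool
the stack by 10, project, run a bidirectional LSTM and flatten the hidden
sequence. Flattening (rather than global pooling) is deliberate: the region
head needs positional layout. The loss is the sum of the two head
cross-entropies; argmax ties break to the lowest class index.

"Match" is implemented as an absolute threshold: the element-wise maximum of
the two selected-MSRL curves must reach ≥ 0.5 (configurable) somewhere in
the predicted 40 bp bin. Whether a "significant peak" should instead be
relative-to-background or statistical is genuinely open; the absolute rule
is monotone in the threshold (property-tested) and auditable.

The ensemble holds ten members — five CNN, five LSTM, widths spanning small
to large, distinct seeds; `test_scale` widths are 8–32, `paper_scale` widths
192–448. The screening decision uses the ensemble-*averaged* head
probabilities (not a vote of argmaxes); the Match tally is a separate count
over members, and ≥ 7/10 Matches gate the recommendation.

## Screening

The rewrite window is the MSRL-length window centred on the argmax of the
averaged selected-MSRL curves within the selected region, clipped to
[0, 400) — peak-centring is the natural reading of a probability track, and
clipping can push the window partly outside the nominal bin at the promoter
edges. The rewritten sequence replaces the window with the TFBS, so its
length is 400 − MSRL + |TFBS| and every base outside the window is conserved
(asserted on every proposal). Display coordinates are ATG-relative: position
p ↦ p − 400, half-open on the right. A proposal is flagged
`element_disruption` when the window intersects an annotated TATA-box
(modelled 8 bp wide) or TSS (1 bp), `no_consensus` below the Match
threshold; recommended ⇔ no flags. Ranking is lexicographic
(n_match ↓, mean peak ↓, promoter id ↑) — consensus first, confidence
second, deterministic tie-break. One OQPR indexing subtlety: a worked
region-3 window at −277…−237 is consistent with proximal-first bin
numbering, whereas this package numbers bin 1 as most distal; the convention
is documented here rather than asserted as canonical, and `to_display_coords`
is tested on the span arithmetic itself.

Split-site (two-operator) designs need no special machinery: re-run
`recombine` on an already-rewritten promoter.

## Random-placement baseline

The chance level for base-level precision is computed two ways: exact
enumeration over all (M+1)² start pairs (M = N − L), and seeded Monte-Carlo
with a reported standard error; the suite requires agreement within 3 SE
across an (N, L) grid. For N = 400, L = 5 the exact value is
9860/(5·396²) ≈ 1.26 %. For L = 40 the pure geometry gives ≈ 10.7 %; with
annotation-dependent avoid-regions (which shrink the start space and raise
the collision probability) the value rises, so only the geometry-dominated
5 bp figure is treated as a reproducible constant. An untrained place-back
model emits label-independent positives, so its expected precision equals
the mean true-window coverage probability — within ~5 × 10⁻⁵ of the
two-window closed form at N = 400, L = 5 — which is the calibration the
suite checks (tolerance 3 SE + 0.001 absolute, the slack covering exactly
that analytic edge-effect gap).

## Assay metrics

The tetO metrics follow the δ-corrected definitions (module docstring of
`promplace.assay` spells out all four formulas). The identity
repression = 1 − 1/fold holds exactly by construction, and both printed-pair
checks in the suite ride on it; reported (rate, fold) pairs that violate the
identity slightly are rounding artefacts of underlying replicate means, and
the module reports the residual rather than reconciling it. When
repressor-free controls are absent, δ defaults to 1 with a warning — the
correction is an adjustment, not a requirement — and the disruption rate is
NaN unless the wild-type reference exists. Replicate tables are reduced to
per-replicate metrics and then mean ± sd; analysis of variance across
replicates is out of scope.

## Problem sizes and limitations

The suite trains only desk-scale models: the memorization check runs a
test-scale place-back for 150 steps on 20 fixed samples; determiner recovery
trains a 16-channel CNN for 150 steps on idealised indicator stacks;
calibration evaluates an untrained model on 1,000 samples; the Monte-Carlo
baseline uses 10⁶ draws. These sizes were chosen so the whole suite runs in
a few minutes on one CPU while still exercising every training and inference
path. Consequences: trained-model precision/recall at full scale is not
reproduced or claimed; determiner accuracy is demonstrated on separable
synthetic stacks, not on real place-back outputs of trained models; and
screening outputs from untrained models are structurally valid but
biologically meaningless. Known limitations beyond scale: the LSTM branch
processes padded query tails (masked only at fusion), the Match rule is an
absolute threshold, and iterative split-site screening shifts coordinates of
any promoter annotations made before the first rewrite.
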