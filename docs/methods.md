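# Methods

## Sequence model and encoder

A protein is its primary sequence S = ξ₁ξ₂…ξ_N over the 20 canonical
residues in alphabetical one-letter order (A, C, D, …, Y). Non-standard
codes (B, Z, X, U, O) are rejected by default; an explicit policy can map
them to a chosen canonical stand-in, because silent coercion would
corrupt the encoder. Sequences are truncated to their first 100 residues
before encoding — the same cut the curation step applies to secretory
records — which also bounds the factorial self-term below.

For each residue type â and each property coupling, the feature
component is

    Π_â = Λ_â + (Λ_â − 1)!·ϑ(ξ_â, ξ_â)
          + [ leading·{X+Y} + Σ internal·{X+Y} + trailing·{X+Y} ]

* Λ_â — occurrence count of â. An absent residue contributes Π = 0 (the
  factorial of −1 is undefined, so the empty profile short-circuits);
  a singleton uses 0! = 1. Factorials are evaluated in log space and
  saturate at 1e300; with the 100-residue truncation Λ ≤ 100 and 99!
  ≈ 9·10¹⁵⁵ is still exactly representable, so the cap only matters if
  the truncation length is raised.
* Gap factors — with 1-based occurrence positions p₁ < … < p_Λ, the
  leading factor is p₁ (dropped when p₁ = 1), the internal factors are
  the consecutive differences, and the trailing factor is N − p_Λ
  (dropped when the last occurrence is terminal). Internal gaps telescope
  to p_Λ − p₁, which the vectorized encoder exploits.
* {X+Y} — (1/38)·[Σ_{k≠â} f(k→â)·ϑ(ξ_k, ξ_â) + Σ_{k≠â} f(â→k)·ϑ(ξ_â, ξ_k)]
  where f are directed immediate-adjacency counts ("pair exists" means
  immediate adjacency; any-co-occurrence would make the existence matrix
  almost always all-ones). Absent pairs contribute zero. The same value
  weights every gap factor of â, and 38 = 2·19 is the number of directed
  pair classes around a residue; no length renormalization is applied.

The pair function for scheme s ∈ {1, 2, 3} (hydrophobicity,
hydrophilicity, side-chain mass) is

    ϑ(l, m) = √(Δ*_s(l)²·|Δ*_s(l) − Δ*_s(m)|²)
            + |(Δ*_a(l) − Δ̄*_a)(Δ*_b(m) − Δ̄*_b)| / √(Σ(Δ*_a−Δ̄*_a)²·Σ(Δ*_b−Δ̄*_b)²)

with cross pairs (a, b) = (1,2), (1,3), (2,3) for the three schemes, the
first-term property tied to the scheme id (an override is available for
sensitivity analysis, since the coupling choice is a convention), and
means/sums over the 20-residue alphabet. Both terms are non-negative.

Scales are shipped as a versioned TSV: Tanford hydrophobicity,
Hopp–Woods hydrophilicity and integer textbook side-chain masses. Each
scale is standardized onto (−R, R) by the affine map
Δ* = [2R/(Δ_max − Δ_min)]·(Δ − Δ_max) + R, so the extreme residues sit at
exactly ±R. R defaults to 1: the unit half-width keeps the three
properties' pair-function magnitudes commensurate, and any other choice
only rescales the property blocks jointly. Absolute feature values are
therefore reproducible only relative to these shipped tables.

**Vector layout (220 elements).** Per property, the 20 components are
split into three additive sub-blocks — core (Λ + self-term +
internal-gap sum), leading-gap and trailing-gap — giving 60 features per
property whose sub-block sums recover Π exactly. The three sub-features
are precisely the three terms the boundary constraints toggle, so the
split adds positional boundary information without losing any. The final
40 elements are the 20 length-normalized compositions Λ_â/N and the 20
length-normalized mean positions (0 for absent residues). The test suite
checks the whole construction exhaustively against a literal term-by-term
expansion on all 5,456 sequences of length 2–6 over {A, C, D, E}.

## Classifier

A 220–50–2 network, sigmoid activations in both layers, full-batch
gradient descent on the mean squared error against one-hot targets
(secretory = (1,0)). Weights initialize uniformly in ±1/√(fan-in),
seeded. The learning rate starts at 0.5 and adapts: ×1.05 after a
loss-reducing epoch (capped at 50), ×0.7 with the step rejected after a
loss increase (training stops below 1e-8, after 300 epochs, or when an
accepted improvement falls below 1e-10). MSE and the specific adaptive
constants are this package's choices — classical defaults for this
architecture — and the accepted-step loss sequence is non-increasing by
construction.

Feature columns are standardized to zero mean and unit variance on the
training set (parameters stored in the model) before entering the
network. This is a deliberate addition: the factorial self-term makes
raw feature magnitudes span ~10 orders, which saturates sigmoid units
and stalls gradient descent. Standardization is part of the model file
and can be disabled in the config.

Prediction returns (class, score) with class the argmax of the two
output units — an exact tie resolves to non-secretory, the conservative
call — and score the secretory unit's output in [0, 1], used directly
for ROC analysis. Models serialize to a versioned JSON document.

## Cleavage-site detection

Counts P(â, i) of residue â at aligned window position i over training
windows give the log-odds matrix

    Q(â, i) = ln( (P(â, i) + c) / (⟨P(â)⟩·(n + 20c)) )

with background abundances ⟨P(â)⟩ and pseudocount c = 1 by default (the
logarithm is undefined on zero counts; c = 0 is allowed and produces
−inf sentinels). When positional frequencies equal the background
exactly (c = 0), Q vanishes identically. The aligned window is −13…+2
relative to the cleavage bond: it covers the h-region signal while
keeping two mature-side contrast columns; spans from −15…−10 on the left
to +2…+8 on the right changed site recovery by under one percentage
point, so the compact default is kept. It is configurable.

The (−3, −1) rule sets are, for eukaryotes: −1 ∈ {A, S, G, C, T},
−3 ∈ {D, E, K, R, N, Q} with {F, H, Y, W} explicitly forbidden, and no
proline anywhere in −3…+1. For prokaryotes: −1 ∈ {A, G, S, T},
−3 ∈ {A, G, L, S, T, V}, same proline exclusion; the tendency for −7/−8
to be hydrophobic (not V/F) is recorded on the rule set but not enforced
as a hard constraint, since it is a statistical preference rather than a
rule. The eukaryotic −3 set is implemented exactly as the source model
states it even though it differs from the classical small-residue
(−3, −1) sets; `get_rules("eukaryote", classic_von_heijne=True)` selects
the classical alternative — no silent correction is made.

Scanning walks candidate +1 positions 4…min(60, N−1) (signal length
3–60). Non-compliant positions are zeroed out of consideration; each
compliant site is scored by summing Q over its aligned window, with
out-of-bounds window positions contributing nothing (equivalent to
assuming background composition beyond the termini). The site is the
score spike: the maximum, with exact ties resolved to the most
N-terminal candidate. The scanner can never return a rule-violating
site, and with a uniform matrix it degenerates to pure rule filtering
plus the tie-break — both properties are tested.

## Evaluation

The prediction rates Υ⁺ = 1 − FN/T⁺, Υ⁻ = 1 − FP/T⁻ and
Υ = 1 − (FN+FP)/(T⁺+T⁻) coincide with Sn, Sp and Acc; MCC is computed in
the confusion-matrix form, and an algebraically identical prediction-rate
form is kept as a separate code path so the identity can be
machine-verified (it holds exactly; the suite checks both identities on
10,000 random tables). Undefined statistics (empty class, zero marginal)
are NaN sentinels rather than silent zeros. Reports display at 2
decimals.

ROC curves use a descending threshold sweep with trapezoidal AUC,
verified to 1e-9 against the pairwise ranking-probability
interpretation and against an independent reference implementation.

Protocols: self-consistency (train = test), stratified k-fold (k = 10;
folds are stratified because unstratified small folds can be
single-class, leaving Sn/Sp undefined; the overall figure is the average
of fold accuracies), and the jackknife (leave-one-out with a full
retraining per item; a `fast_approx` mode evaluates one full-data model
instead and is never used for reference numbers). Every fold retrains
from the same seeded initialization, so the partition alone determines
the outcome and k = n cross-validation coincides exactly with the
jackknife.

## Curation

Input is a flat TSV (id, oc, location, signal_start, signal_end,
keywords, sequence) standing in for a knowledgebase export; live
database querying is out of scope, and a real export can be flattened
into this dialect. Secretory records need a signal-peptide annotation
and none of the (case-insensitive, substring-matched) exclusion keywords
"potential", "probable", "fragment", "by similarity"; their first 100
residues are extracted. Non-secretory records are nucleus/cytoplasm for
eukaryotes, cytoplasm for prokaryotes, and are not truncated (the
truncation is stated only for secretory extraction). Exact-duplicate
sequences are removed; no homology-based redundancy reduction is
attempted. The step is idempotent.

## Synthetic data

The generator emulates the tripartite signal architecture with planted
ground truth: n-region of 1–5 residues from a basic-biased pool with at
least one K/R; h-region of 7–15 residues from a leucine-rich hydrophobic
pool; c-region of 3–7 polar residues whose −3/−1 positions are drawn
from the organism's allowed sets (so every positive passes the rule at
its planted site by construction, which is asserted, not assumed);
mature region of 30–80 residues and negatives of 50–150 residues from a
typical globular-protein composition. Region-length ranges follow the
classical description of signal anatomy; the pools are this package's
choices of realistic biases. Everything derives from one seed.

What the generator does not emulate: homology between sequences,
organism-specific codon/composition idiosyncrasies, signal peptides with
atypical (very long or charged) h-regions, and annotation noise. Passing
tests on this data therefore demonstrate that the pipeline recovers the
structure it models — clean separability and plantable cleavage sites —
not performance on real proteome-scale data, where published tools of
this family report lower site accuracy.

## Problem sizes and reference numbers

The reference computation (`scripts/acceptance.py`) uses the default
study conditions: 200 + 200 generated sequences, self-consistency and
stratified 10-fold cross-validation on all 400, jackknife on a
stratified subsample of 100 (one retraining per held-out item keeps the
400-fold variant disproportionate to what it adds), and cleavage-site
recovery over the 200 positives with the weight matrix built from their
own annotated windows — the self-consistency analogue for the scanner.
With a held-out matrix (built on an independently generated set),
recovery drops to ≈ 93%: about one positive in seven has a genuinely
rule-compliant site one to three residues from the planted one, because
the c-region's composition overlaps the allowed −1 set — an ambiguity
real signal peptides share. Typical outputs: self-consistency accuracy
100%, 10-fold CV 90–92%, jackknife 85–90%, site recovery 96–98%.

## Known limitations

* Absolute feature values depend on the shipped property tables and
  R = 1; other tables change the numbers (not the structure).
* The network is a fixed two-layer sigmoid MLP; no early stopping on a
  validation split (the protocols own the splitting).
* The weight matrix assumes positional independence within the window,
  as any PWM does.
* The jackknife retrains per item and is O(n) trainings; use the k-fold
  protocol or the documented subsample for large n.
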