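# Methods

## Model overview

wholemir treats miRNA targeting as a two-stage problem: a cheap,
permissive *candidate-site selection* stage that narrows the search space,
and a learned *site classifier* that decides functionality from raw
sequence. The design assumption is deliberately minimal: no hand-crafted
descriptors (conservation, AU content, pairing energies) enter the
classifier — only the one-hot transcripts — so whatever pairing logic
matters must be learned from the labeled examples. Exogenous information
that cannot be inferred from the miRNA:site duplex (site accessibility)
enters, if at all, as an *a posteriori* filter on the candidate list.

## Candidate-site selection

A 30 nt window (large enough to host a duplex with bulges) slides along
the 3'UTR in 5 nt steps; a shorter UTR contributes one whole-UTR window
rather than none. Each window is cofolded with the miRNA; the joint MFE
structure supplies (i) a stability gate — windows must bind with strictly
negative free energy — and (ii) the intermolecular pair map on which the
selection rules operate. Only intermolecular pairs count: intramolecular
structure is not a binding contact.

The relaxed rules `6-1:10`, `7-1:10`, `7-2:10` require 6 or 7 paired miRNA
positions (WC or G:U wobble, gaps allowed) inside the extended seed
region, nucleotides 1–10. Two canonical-oriented rules are implemented
for comparison: a TargetScan-style rule (perfect WC seed 2–8; or exactly
one seed defect offset by ≥ 3 consecutive WC pairs within 13–16; or 11
contiguous WC pairs within 4–15) and a PITA-style rule (perfect 7mer at
1–7 or 2–8; or one defect in the 1–8 region with ≥ 7 WC pairs there).
A "defect" is a seed position with no intermolecular pair, or a wobble
where WC is demanded. For the centered clause we implement the
11-contiguous-pairs definition; a 4mer-at-10–14 variant exists in
circulation and is noted here but not used. Overlapping accepted windows
are kept as distinct candidates; the 5 nt step already keeps window
redundancy minimal.

The relaxed rules are designed supersets of the canonical ones; the
package tests this empirically over enumerated pair maps rather than
asserting it, because a TargetScan-compensatory site with few total pairs
in 1–10 can in principle escape `7-1:10`.

## Thermodynamics backends

All folding goes through one backend contract: `cofold(a, b)` returning a
joint MFE dot-bracket + energy, and `ensemble_energy(seq, unpaired=...)`
returning constrained/unconstrained ensemble free energies. The
`reference` backend adapts ViennaRNA. The `toy` backend assigns −1.0
kcal/mol per WC pair and −0.5 per wobble in the best ungapped antiparallel
alignment and has no intramolecular structure; it exists so that every
pipeline property can be verified against brute-force enumeration with no
external engine, and so the full pipeline runs deterministically in tests.

**Site accessibility.** ΔG_open is computed as
E(ensemble) − E(ensemble | site unpaired) on up to 200 nt of UTR centered
on the site (truncated at UTR ends — flanking sequence is never invented).
Under this convention ΔG_open ≤ 0; a large negative value means strong
local structure must be opened. The filter retains sites with
ΔG_open ≤ th_sa and the default th_sa = −10 kcal/mol; the accessibility
literature also uses the opposite (positive-cost) sign convention, so the
convention identifier is carried in every result and the threshold and
comparison direction are configuration, not constants. Values within
1e−6 of zero snap to exactly 0 so unstructured contexts report no cost.

## Input encoding

Each nucleotide maps to 4 bits (A 0001, C 0010, G 0100, U 1000; empty
0000). The miRNA occupies 30 left-aligned slots (120 bits) — 30 slots
accommodate the longest known mature miRNA, and left-alignment pins the
seed region to fixed input nodes. The site occupies a fixed 40-slot frame
(160 bits): slots 0–4 upstream flank (right-aligned against the site),
5–34 site, 35–39 downstream flank, all in mRNA 5'→3' orientation.
Boundary-truncated flanks leave their slots empty, so the first site
nucleotide always lands on the same input node. The site's orientation
relative to the miRNA is a convention, not a fact fixed by the biology;
it is versioned (`one-hot/v1`) and saved with every model, and a model
refuses to score inputs produced under a different version.

## Network and training

Architecture: 280 inputs → ReLU hidden layers 400, 250, 150, 80, 40
(encoder), 40, 20, 10 (classifier funnel) → 2 softmax outputs. The first
layer is wider than the input (over-completion: room to expand the
representation before compressing); layers 1–5 are the encoder half of a
stacked autoencoder and can be pretrained to reconstruct the inputs
before supervised training. Exact layer widths are configuration; the
defaults honor over-completion, a five-layer compressing encoder and a
three-layer funnel.

Supervised training: Adam (rate 1e−3), mini-batches (128 default; the
acceptance experiments use 64, which generalized better on the synthetic
corpus), inverted dropout 0.2 on every hidden layer, epoch cap 500, and
best-validation-epoch weight selection (ties → earliest epoch). Both
`XENT` (softmax cross-entropy) and `NLL` (negative log-likelihood of the
observed class) are accepted as loss settings; with softmax outputs and
one-hot targets they are analytically the same quantity, and both are
kept only so either convention can be named in configs. Training is
bit-for-bit reproducible from the configured seed on one thread; the
implementation is plain NumPy — at these layer sizes dense matrix
products are all that is needed, and carrying a tensor framework would
add nothing but weight.

Site decision: class = sign(o₁ − o₀) with ties negative; a grey-area
margin K ≥ 0 turns low-confidence calls into "unknown" (score in
(−K, K)). Unknown calls never fire the gene-level disjunction and are
excluded from confusion metrics, where their share is reported as a
coverage fraction instead — folding abstentions into either class would
silently mix calibration into accuracy.

## Autoencoder pretraining and what it can achieve

The encoder plus a mirrored ReLU decoder is trained to reconstruct the
one-hot input, read out as a 5-way softmax per nucleotide slot
(A/C/G/U/empty) under cross-entropy. The *reconstruction relative error*
is the fraction of slots whose argmax-decoded symbol differs from the
input, measured on a 10% held-out split; pretraining stops when it drops
below 0.05 or at the epoch cap (in which case the weights reached are
kept, with a warning). A per-input-unit squared error is reported
alongside as a calibration diagnostic.

A limitation worth stating plainly: on corpora whose site windows carry
random flanking context — which includes both the synthetic corpus and
real UTR sequence — roughly a quarter of the input slots are
incompressible, so held-out reconstruction cannot approach the 0.05
target no matter the bottleneck width or training scheme (greedy
layerwise, progressive deepening and joint training all plateau between
0.22 and 0.33 symbol error; the corresponding per-unit squared error
plateaus near 0.10 against an entropy-accounting optimum of ≈ 0.06).
Training-set reconstruction does reach 0.03–0.05. The pretraining is
therefore useful as an initializer, but its held-out stopping criterion
is not reachable on this kind of data and the epoch cap is the expected
exit; the acceptance suite keeps the strict criterion and reports the
failure honestly rather than weakening it.

## Dataset construction

Site examples are miRNA:site pairs, not miRNA:gene pairs. Negatives are
mined: every stable window (ΔG_duplex < 0) of a negatively-labeled pair's
UTR becomes one negative example. Positives come from annotated site
intervals subject to the same stability gate; annotated sites failing it
are dropped with a warning. Positive pairs lacking coordinates can be
mined instead, labeling CSSM-accepted stable windows positive — those
carry `mined_window` provenance so downstream users can exclude them.

Cross-validation is random-subsampling: each fold independently draws
~66.67% of examples for training (within one example), walking miRNA
families in shuffled order and drawing both classes from each family
against per-class quotas, which preserves the global class ratio (±1) and
gives every sampled family both classes where possible. Families with a
single class are confined to training with a warning. Held-out examples
sharing a miRNA family *or* an exact site sequence with the fold's
training sample are excluded from testing (the stricter union of the
pair-level and family-level readings of the overlap rule); the boundary
family that straddles the quota is partially trained and its remainder
excluded likewise.

## Synthetic corpus

The generator emulates the shape of CLIP/CLASH-derived training corpora:

* miRNAs 18–25 nt, grouped into families of 3 sharing the extended seed
  (positions 1–10); ~12 site examples per miRNA, matching the density of
  curated corpora (tens of thousands of sites over a few thousand miRNAs).
* UTRs 100–2,000 nt of uniform random sequence, one per example, with the
  site window implanted on the 5 nt scanning grid.
* Planted sites are built from the miRNA's reverse complement with a
  controlled pairing profile. Positives (default grammar) pair ≥ 7 of
  seed positions 1–10 (up to 2 as G:U wobbles) and carry full WC pairing
  at 13–16 (3' compensation); a `canonical` grammar plants perfect WC
  7mers at 2–8 instead. Negatives are *near-misses*: ≤ 5 seed pairs with
  scattered (p = 0.6) 3' pairing — still a stable duplex, as mined
  negative windows are, but without the dense 3' complementarity of a
  functional site. The duplex region is right-aligned in the window so
  the seed complement occupies consistent input nodes, matching the
  seed-aligned input layout.
* Optional label-flip noise; classes alternate, so even n is exactly
  balanced; everything is deterministic from one seed.

What passing tests on this corpus do and do not show: they demonstrate
that the pipeline's machinery is sound and that the network can extract a
planted extended-seed + 3'-compensation pairing grammar from raw one-hot
input (held-out AUC ≈ 0.93–0.96 at 10,000 pairs, chance on permuted
labels). They do not demonstrate performance on biological corpora: real
positives are not generated by a clean rule, real negatives are not
guaranteed near-misses, UTR composition is not uniform random, and the
real site-position distribution inside CLIP windows is unknown.

## Numerical and procedural choices

* Energies are kcal/mol; threshold comparisons are strict where the rule
  says "negative" (ΔG_duplex < 0) or "higher than" (ΔG_open > th_sa
  removes).
* Eq-style tie at o₁ − o₀ = 0 classifies negative; with K = 0 the
  grey-area rule is checked to coincide pointwise with the sign rule.
* Gene score for ranking/ROC is the maximum site score, −1 when no site
  survives; this is an artifact convention — the gene verdict itself is
  the disjunction, which defines no score.
* ROC/AUC uses the standard threshold sweep with trapezoid integration
  and midrank tie handling (scikit-learn), cross-checked in tests against
  the Mann–Whitney U probability.
* Metrics with empty denominators are reported as undefined (`None`),
  never as 0.
* Problem sizes in the acceptance computations — 10,000 pairs for
  learnability, 2,000 for pretraining, 1,000 genes for filter soundness,
  131,071 enumerated pair maps for the selection-rule oracle — were
  chosen as the smallest sizes at which each claim is meaningfully
  testable on a single CPU.

## Known limitations

* Site-level independence: multiple weak sites acting in concert are not
  modeled; the disjunction sees each site alone.
* The false-positive model 1 − precisionⁿ assumes independent site
  errors; overlapping windows violate independence mildly.
* The ΔG_open sign convention in the source literature is ambiguous;
  both threshold and comparison direction are exposed in configuration.
* The autoencoder's held-out reconstruction target is unattainable on
  corpora with incompressible flanking sequence (see above).
* The toy backend's energies are a counting model, not thermodynamics;
  conclusions about real binding energies require the reference backend.
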