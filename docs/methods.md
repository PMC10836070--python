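# Methods

## The evaluation problem

A fold-switching protein has two experimentally determined conformations —
a dominant "ground state" and an alternative ("fold-switched") state. A
structure-prediction protocol aimed at such proteins produces an *ensemble*
of models, and the evaluation question is twofold: does the ensemble contain
accurate, confident models of **both** real conformations, and does it avoid
confident models of conformations that were **never** observed? The second
half matters as much as the first: fold switchers usually have single-folding
homologs, and a protocol that "discovers" fold switching where experiments
show none is worse than one that stays silent.

The pipeline operates entirely on files: an MSA (A3M/FASTA), a directory of
predicted models (PDB, per-residue confidence in the B-factor column, as
AF2/ColabFold emit), two reference structures, and a fold-switching residue
range. Running the predictor itself is out of scope by design — the
integration is a file contract, which keeps the package lightweight and
deterministic.

## Model scoring

**Dual-reference RMSD.** The fold-switching region is extracted from the
model and from each reference (inclusive, 1-based residue-number interval);
residues are paired by sequence (positionally when identical, by global
alignment with a warning otherwise), atoms by name — all shared heavy atoms
by default, CA-only as a fallback for mutants with mismatched side chains.
The model is superposed independently onto each reference with the Kabsch
algorithm (SVD of the covariance of centered coordinates; the determinant
correction restricts the solution to proper rotations, so mirror-image
matches can never score well). Superposition uses the region's atoms only:
scoring the region within a whole-chain frame would mix in hinge motion of
the non-switching flanks. A `fit="whole"` mode exposes the alternative
convention.

**Classification.** With thresholds (defaults in parentheses): a model is
labelled `ground` or `alternative` if its smaller region RMSD is within
`accurate_rmsd` (3 Å) of that reference, else `neither`; equal RMSDs break
toward ground with a logged warning (they indicate a degenerate reference
pair, not a meaningful call). The model is *accurate* when labelled and its
mean region plDDT is at least `accurate_plddt` (55), and *high-confidence*
at `high_conf_plddt` (70). plDDT is averaged over the fold-switching region
— the region is what is being predicted; a model can be confidently wrong
there while the rest of the chain is easy — with the whole-chain mean
available by flag. `poor_rmsd` (5 Å) marks models far from experiment in
reports.

**False positives and verdicts.** A false positive is a high-confidence
model that matches neither reference, or matches a conformation absent from
the protein's experimental record. A conformation counts as *predicted*
when at least one accurate, high-confidence model of it exists; a protein
with both conformations predicted is called metamorphic, with exactly one,
a single folder.

**Ensemble statistics.** The confusion table takes one decision per
(protein, conformation) pair: predicted (as above) vs experimentally
observed. MCC uses the standard closed form. Degenerate tables (a zero
marginal) need a convention: an error-free table (FP = FN = 0 with at least
one correct decision) scores 1.0 — a single metamorphic protein perfectly
recovered should not score 0 merely because no negative decision exists —
and every other degenerate table scores 0. %success is the fraction of
decisions correct; the per-model success rate is the fraction of accurate
models, reported at full precision plus nearest-integer rounding (10/250 →
"4%", 5/21 → "24%"). Runs-per-ensemble counts distinct `run_id`s in the
ensemble manifest (one run per model absent a manifest), capturing the cost
asymmetry between protocols that need a couple of runs and those that need
hundreds. No multiple-testing machinery: these are descriptive metrics.

## MSA operations

A3M rows are normalized by deleting lowercase letters (insertions relative
to the query), so every row lives in the query's column space; the alphabet
is the 20 amino acids, X, and the gap. Clustering is DBSCAN on Hamming
distance expressed as the fraction of differing columns (identical, up to a
factor of 2/22, to Hamming distance between the one-hot encodings), with
`min_samples = 3`; `eps` is either given or chosen by scanning a range and
keeping the value maximizing the number of clusters of size ≥ `min_samples`
(ties: least noise, then smaller eps). These defaults are assumptions — the
clustering protocols in circulation do not pin them down — and all three
knobs are exposed. Random subsampling keeps the query first and draws
`max_seq + max_extra_seq − 1` further rows uniformly *without* replacement
(a single draw: splitting the quota between "cluster" and "extra" sequences
is the inference engine's concern); per-protein presets are max_seq = 1, 8,
64 for KaiB, Mad2, RfaH with max_extra_seq = 2·max_seq. Pairwise identity
divides matches by columns non-gap in both sequences. Every stochastic
operation takes an explicit integer seed; there is no global RNG state.

## Synthetic data: what it emulates, and what it does not

The generator produces every pipeline input with known truth:

* **Reference pairs** — one random sequence built twice from backbone
  internal coordinates (N, CA, C, O; ideal bond lengths N–CA 1.458 Å,
  CA–C 1.525 Å, C–N 1.329 Å, C=O 1.231 Å; trans peptides): helical
  (φ = −57°, ψ = −47°) over the region in the ground state, extended
  (φ = −139°, ψ = 135°) in the alternative, identical helical flanks.
  Construction verifies the conformers are > 5 Å apart over the region
  (the 60-residue default with region 21–50 gives ≈ 16.7 Å).
* **Decoys** — a base conformer plus i.i.d. Gaussian coordinate noise with
  σ = target_rmsd/√3 (from E[RMSD²] = 3σ²); the ~1–2% downward bias from
  re-superposition and the concavity of the square root is well inside the
  10% calibration tolerance. Hybrid decoys splice ground coordinates before
  a split residue onto alternative coordinates after it, rigidly aligned at
  a 3-residue junction window — emulating the hybrid-fold artifact real
  predictors produce, which matches neither reference.
* **MSAs** — two founders differing at ⌈divergence·L⌉ positions (default
  0.6), members mutating each position at rate 0.05. Expected intra-subfamily
  distance ≈ 2·0.05 column-fraction and inter ≈ 0.6, leaving a wide eps
  valley around the 0.3 used in tests.

What passing tests on this data do **not** show: anything about real
predictor behaviour. Synthetic decoys have isotropic, residue-independent
error; real model error is correlated along the chain and concentrated in
flexible regions, real plDDT correlates with local accuracy rather than
being set by the generator, and real MSAs have phylogenetic structure far
richer than two subfamilies. The synthetic suite validates the *measuring
instrument* — RMSD mathematics, thresholds, bookkeeping, determinism — not
any claim about which prediction protocol is better on real proteins.

## Numerical choices

* Kabsch requires ≥ 3 points and rejects configurations whose second
  singular value is ≤ 1e-8 of the largest (collinear sets leave the
  rotation under-determined).
* plDDT scale auto-detection: if every B-factor is ≤ 1.5 the file is taken
  to use the fractional 0–1 convention and rescaled by 100.
* PDB round-trips are exact to the format's 3-decimal coordinate precision;
  report files use fixed float formats and sorted JSON keys, so re-runs are
  byte-identical.
* Subsampled alignments and cluster labels are deterministic functions of
  (input, seed) — `numpy.random.default_rng` throughout.

## Problem sizes

Tests and the acceptance script use 60-residue chains (120 region atoms),
ensembles of 7–13 models, 20 generator seeds for recovery properties, 100
seeds per calibration target, and 200 seeds for subsampling balance on a
1001-row MSA — sizes at which every property being asserted is already
fully expressed.

## Known limitations

Backbone-only decoys (no side chains, no clash relief, only two dihedral
basins); single-chain PDB handling (no mmCIF, first model only); no
TM-score/GDT/lDDT alternatives to RMSD; the eps/min_samples defaults for
clustering are conventions, not fits to any published run; and the
(protein, conformation) confusion unit is one documented choice among
several defensible ones (a per-model unit is available via the underlying
`confusion` primitive).
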