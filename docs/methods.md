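# Methods

## The PPP statistic

Given a phylogenetic profile over a collection of N genomes with
n_yes genomes carrying the query family, set p = n_yes / N. For a protein
with a ranked similarity hit list, walk depths d = 1, 2, … consuming one
list entry at a time. A genome enters the distinct-genome set once, no
matter how many of its proteins appear in the list; after entry d the set
has n(d) genomes of which k(d) are YES. Each depth is scored by the
binomial upper tail P(X ≥ k | n, p), and the protein's score is the most
negative log₁₀ tail over all depths, ties broken toward the smallest
depth (which makes results stable under list truncation). Reports store
the signed log₁₀ tail; ranking uses its negation.

Model assumptions worth keeping in mind:

* Genomes are treated as independent Bernoulli trials — no correction for
  phylogenetic correlation among related genomes. The statistic is a
  ranking device, not a calibrated p-value.
* The depth is maximised over, and no multiple-testing correction is
  applied across the proteins of a genome; scores are comparable within a
  run, not across profiles with different p.
* The query's own self-hit is included by default (its genome is YES by
  construction when the query belongs to the family); `include_self=False`
  removes it for scoring a protein against a foreign profile.
* p defaults to the profile's own n_yes / n_total and can be overridden
  (`p_override`) to pin a specific denominator, e.g. when reproducing
  scores computed on a slightly different collection size.

### Numerical contract

The tail is computed entirely in log space: term logs
log C(n,i) + i·log p + (n−i)·log1p(−p) for i = k…n are combined with
`logsumexp`, which factors out the largest term. This keeps relative
accuracy in log₁₀ units below ~1e-12 for n ≤ 1e4 and returns finite
values far below the smallest normal float (a linear-space survival
function underflows to 0 near 1e-308; tails of 10⁻⁴⁷⁰ are routine here).
P(X ≥ 0) is exactly 1, so k = 0 returns exactly 0.0. Degenerate profiles
(p = 0 or 1) are representable but rejected at scoring time. Results are
memoised on (k, n, p) since a genome ranking re-evaluates few distinct
states.

## Precursor scanning

A cleavage site is any occurrence of a two-residue doublet (default
{GG} only; GA/GS can be enabled but double-glycine is the classic motif)
whose cut position — the index of the first core residue — falls inside
the leader window. The doublet stays on the leader, because the
hypervariable region follows the motif. Defaults, all configurable:

| parameter | default | rationale |
| --- | --- | --- |
| leader window | [15, 150] | spans classic ~24-residue microcin leaders through ~70–90-residue nitrile-hydratase-related leaders, with margin |
| core length | 5–120 | short hypervariable cores; generous upper bound |
| min heterocyclizable fraction | 0.25 | "rich in C/S/T" has no published numeric threshold; 0.25 sits well above the 0.15 uniform-background expectation |
| protein length cap | 250 | precursors are small proteins |
| composition background | uniform 0.05/residue | reproducible default; a proteome-derived background is an option |

Composition statistics exclude unknown residues (X) from denominators; an
all-X or empty core is flagged degenerate with NaN fractions. Candidates
failing a threshold are flagged, never dropped, so downstream stages see
the full scan.

Leader-vs-core conservation uses a minimal Needleman–Wunsch global
aligner (match +1, mismatch −1, gap −1). Identity is counted over the full
alignment length, so a length mismatch is penalised. The traceback
prefers diagonal, then up, then left on score ties; because co-optimal
alignments can disagree on identity, arguments are canonicalised by
lexicographic order before aligning, making the function exactly
symmetric. This deliberately simple scheme is the point: the statistic is
mean pairwise identity contrast (leader vs core), not a substitution-model
alignment.

## Gapless motif models

Short leader motifs are ungapped, so they are modelled as plain
position-weight matrices rather than profile HMMs: per-position
probabilities (count + α)/(N + 20α) with pseudocount α (default 0.5,
Jeffreys-like; α = 0 allowed for exact-identity uses), scored in bits as
log₂(P_pos/P_bg). Residues outside the 20-letter alphabet are
background-neutral (0 bits). The consensus is the per-position argmax with
lexicographic tie-break, and always achieves the model's maximum window
score. A window above 0 bits is likelier under the motif than under the
background; this threshold is analogous to, but not numerically comparable
with, bit thresholds of HMM packages whose null models differ.

## Genome-context classification

Distances are gene-rank (ORF-ordinal) offsets on the same replicon, the
idiom in which cluster adjacency is usually described; strand is recorded
but unused, since no strand rule is established for these clusters. The
default window of 10 ORFs treats "a few ORFs away" as clustered and
anything megabase-distant as not; it is a declared default, always
configurable. Classification is a pure function of the neighbor label
multiset: cyclodehydratase/docking evidence (CD fused, or C and D, or
C-or-D plus B) calls TOMM; LanM calls LANTHIONINE; both present calls
AMBIGUOUS — with both machineries in reach the chemical fate of the
candidate genuinely cannot be called, and the package refuses to guess.
Transport labels alone call TRANSPORT_ONLY (neighboring precursor
paralogs do not block this call); anything else is ORPHAN. Tandem
precursor pairs are consecutive candidates within one ordinal (chains
yield every consecutive pair).

## The synthetic generator

`simulate_collection` emulates the statistical structure the analysis
needs, at desk scale — 200 genomes × 300 genes by default rather than a
full published-scale collection, keeping a 100-seed sweep to about a
minute of CPU. The YES fraction (14/200) is therefore larger than in a
real collection; PPP magnitudes comparable to published report scores can
be obtained via `p_override` when wanted. Planted structure:

* 14 YES genomes, each with 1–12 precursor paralogs: a per-seed 40-residue
  leader template ending in a fixed 13-residue pre-cleavage motif
  ("…ELSDEELEAVAGG"), mutated at 0.05 substitutions/site (the terminal
  doublet is kept intact — the cleavage site is the conserved feature),
  plus a 10–40-residue core drawn with 0.5 combined C/S/T/G mass.
* A modification gene (CD or LanM, alternating per YES genome) placed
  mid-block so every paralog sits within a conservative context window —
  mirroring real clusters, where the enzymes sit inside the cluster.
* A transporter family, itself sequence-conserved, planted next to the
  precursors in 9 of the 14 YES genomes.
* Presence tables with above-cutoff rows for planted families and
  below-cutoff noise rows elsewhere, exercising the trusted-cutoff rule.
* Hit lists scoring within-family pairs by leader-identical positions plus
  Gaussian noise (σ = 2), background pairs sparse and low-scoring, self-hit
  forced first — similarity concentrated in the leader is exactly the
  signal PPP exploits.

What it does **not** emulate: phylogenetic correlation between genomes,
indel evolution in leaders, unequal genome sizes, BLAST score statistics,
or precursors missed by gene callers. Passing the recovery benchmarks
therefore shows the pipeline is correct and well-calibrated on its own
assumptions, not that real collections are this clean.

All sampling flows through one `numpy` Generator seeded from the single
integer seed (hit-list generation uses a second documented substream of
the same seed), so every output is byte-identical across reruns; output
files never embed paths or timestamps, and stage timings go only to the
stderr log.

## Design choices that were genuinely open

* **Distinct-genome counting** in the depth scan (rather than counting
  list entries) is forced by report rows whose optimal depth exceeds n.
* **p denominator calibration**: published report scores are matched to
  three decimals with a 1451-genome denominator and to within 0.01 with
  the stated ~1450; whether one extra genome, a pseudocount, or rounding
  explains this is unresolved, hence the explicit `p_override`.
* **Tie-break at equal scores** toward the smallest depth.
* **PWMs instead of profile HMMs** for motifs: the motifs are defined on
  gapless alignments, so transition structure adds nothing.
* **AMBIGUOUS context class**: added rather than forcing a TOMM/LanM call.
* **Hit lists consumed strictly in order**: score ties at a depth boundary
  are not expanded as a block.

## Known limitations

* The binomial null ignores genome relatedness; closely related YES
  genomes inflate scores.
* The aligner has no affine gaps or substitution matrix; identities on
  distant pairs are conservative.
* PWM bit thresholds are not comparable with HMM E-values.
* The scan's composition prefilter is permissive by design; background
  Gly-Gly sites pass it at an appreciable rate and are expected to be
  removed by context evidence, not by the scan itself.
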