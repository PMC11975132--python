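# Methods

`trnfit` reconstructs a transcription-factor regulatory network (TRN) from
three kinds of input — transcriptomic snapshots, TF motif matrices, and
chromatin-accessibility intervals — by fitting the dissociation constants
of a thermodynamic model of promoter occupancy. This note describes the
model, the numerical choices, what the synthetic data generator does and
does not emulate, and the known limitations.

## Model

### Open chromatin, promoters and gene bodies

Open chromatin is defined operationally: assay-positive intervals
(histone-mark ChIP, DNase-seq, ATAC-seq) that overlap or abut are merged
into connected regions, and a region is kept only if at least one DNase
or ATAC interval supports it. Histone-only regions — including
repressive-mark territory without accessibility — are discarded.
"Connected" means overlapping or book-ended (`end == start`); there is no
gap tolerance. Coordinates are 0-based half-open throughout (BED
convention); GTF input (1-based closed) is converted on read.

A gene's promoter is the open region containing its TSS
(`start <= tss < end`); genes without one are excluded from the network
roster. Gene-body regions are the intersections of open regions with the
TSS-to-TES span, minus any overlap with the promoter. There is no fixed
upstream window: the promoter is whatever connected accessible region the
TSS falls in, which matches the region-based definition the inputs
provide.

### Binding sites and competing repressors

Each TF's JASPAR position-frequency matrix becomes a score matrix:
log-odds against a uniform background (pseudocount 0.8), then min–max
rescaled per matrix so the best possible window scores exactly 1 and the
worst exactly 0. A window's normalized score is its Sp value when the TF
is considered the bound activator, or its Sq value when the same TF
competes as a repressor — same matrices, different roles. `N` bases score
as the per-position minimum, so an ambiguous base can never create a hit.
Matrices whose best and worst windows tie (fully degenerate) are dropped
from the roster with a warning.

Scanning evaluates every window on both strands and greedily retains up
to 4 non-overlapping sites per (region, TF) by descending Sp, ties broken
by offset then strand. The non-overlap rule prevents a single repeat run
from being counted four times. Sites with Sp < 0.5 are not listed — the
floor bounds network density; without it every TF would carry four
near-random sites on every region.

For each retained site, the strongest competing repressor is the TF
(other than the site's owner) maximizing `10^(-a(1-Sq)) * [R] / Ki` on
the site's window, where [R] is the candidate's concentration in the
*initial* expression state and Ki = 1 at selection time (dissociation
constants are not yet fitted). Candidates wider than the site's window
cannot compete. If the best criterion value is below the value it would
take at Sq = 0.5 with [R] at the roster median, no repressor is attached.
Ties break to the lexicographically smallest TF id, so selection is
invariant to enumeration order. Repressor selection runs once, before
fitting, and the network topology then stays fixed — the alternative
(re-selecting as concentrations evolve) would make the objective
discontinuous in Kd.

### Occupancy and transcription

For a gene-region pair bound by activator A at concentration [A] with
sites Sp1..Spp (p <= 4), each site contributes a saturating term with
exponential score weighting `w = 10^(-a(1-Sp))`:

    r = sum_p  w_p [A] / (Kd + w_p [A] + w_q (Kd/Ki) [R])

where the repressor term uses the site's selected antagonist R (zero when
none). When the summed top-4 scores exceed the super-enhancer threshold
(default 3.0), the pair switches to a cooperative Hill-type form,

    r = sum_p w_p [A]^p  /  (Kd^P + sum_p w_p [A]^p + sum_q w_q (Kd/Ki) [R]),

with P the number of sites, which preserves 0 <= r and reduces to
saturation-like behaviour for one site. The transcription flux a single
activator contributes is `kc * exp(-1/r)` (defined 0 at r = 0 by
continuity); it saturates at the basal constant kc, which absorbs RNA
polymerase concentration, the chromatin constant and RT.

A gene's net flux sums activator contributions over its promoter-bound
TFs, subtracts the same functional form for TFs annotated repressor-only
and for all TFs bound in the gene body (gene-body binding is treated as
repressive), and clamps at zero. Ki is one constant per TF — a TF's
dissociation constant *is* its inhibition constant when it acts as the
competitor — and tracks the fitted Kd unless an explicit Ki table is
supplied.

### Degradation and the state update

Nuclear protein loss follows Michaelis–Menten kinetics with the
concentration scale fixed by the Michaelis constant (Km = 1 in expression
units). The exact one-time-unit solution of `dx/dt = -d x/(1+x)` is

    g(x) = W(exp(x + log x - d)),

with W the principal Lambert W branch, evaluated as
`wrightomega(x + log x - d)` which is overflow-free for large x. The
update per learning step is `x' = f(x) + g(x)`, applied synchronously to
every roster gene. TFs whose encoding gene has no open promoter act as
frozen inputs: their concentration stays at its initial value.

A structural property worth knowing: the update map generically has no
interior fixed point. Removal per step saturates at d while the
thermodynamic flux saturates at a constant, so trajectories either decay
toward zero or grow roughly linearly once saturated (we verified this
numerically over a (kc, d) grid). The method is therefore used over
short horizons — 20 learning steps in the default protocol — and
nothing in the fitting below requires stationarity.

## Fitting

The fit adjusts log10(Kd) of every unclamped TF so that iterating the
forward model from the initial expression state for `inner_iterations`
steps (default 5) approaches the reference expression state. The loss is
a weighted squared error on log1p concentrations with weights
proportional to the reference concentrations plus a uniform floor,
`w_g = 1/2 + x_ref,g / (2 mean(x_ref))`. Pure reference-proportional
weighting has a blind spot this floor removes: a perturbation that
silences a gene drives its reference expression — and hence its weight —
to zero, erasing from the objective exactly the genes that carry the
perturbation's signature. The floor keeps every gene visible while still
emphasizing abundant ones.

Gradients are central finite differences on log10(Kd) (step 1e-4),
evaluated for all TFs in one batched forward simulation. Because
occupancy depends exponentially on motif scores, the loss surface has
extreme curvature: a fixed step size either diverges or crawls. Each
descent step therefore moves along the gradient direction normalized to
unit maximum entry, with a backtracking line search: candidate steps on
the geometric ladder `learning_rate * 2^-k` (k = 0..12, default maximum
step 1.0 in log10 units) are evaluated in one batch and the
loss-minimizing candidate is accepted only if it decreases the loss.
The loss trajectory is non-increasing by construction. log10(Kd) is
clipped to ±6 during descent; clamped TFs (`fixed` map) keep their given
value bit-identically. The descent runs a fixed number of steps
(default 20) and records the full Kd trajectory. It is deterministic
given its inputs and invariant to TF roster ordering (rosters are
canonicalized internally).

Derivative factors — the sensitivities of each gene's promoter term and
gene-body term to each regulator's concentration — are computed at the
fitted state by central differences with a relative step (1e-5 scaled by
concentration), checked against step-halving to 1e-5. They are the edge
weights of the exported digraphs (Act_list.csv / Rep_list.csv /
GraphML); edges run regulator -> target. A regulator reaching the same
target through both the promoter and the gene body yields two parallel
edges of opposite sign, so the graph is a multigraph.

## Core-TF analysis

A core TF is one whose fitted Kd moved from its initial value:
`|log10(kd_final / kd_init)| > tolerance`, default 0.5 (≈ 3.2-fold),
clamped TFs excluded. Comparing a condition fit against a control fit
gives per-TF Kd ratios; the maximum ratio reads as the most inhibited TF
in the condition (higher Kd = weaker binding), the minimum as the most
activated. Ratio-mode digraphs divide condition derivative factors by
control ones, dropping entries whose control value is below 1e-12.

As a robustness control, `control_reference` replaces the reference
expression by seeded uniform noise or a constant vector; core TFs that
persist under such null references reflect network structure rather than
the reference signal and should be discounted.

## Synthetic data generator

The generator emits a complete input set — one-chromosome genome FASTA,
GTF gene models on both strands, per-assay peak BEDs whose merged unions
reproduce the intended promoter and gene-body regions plus histone-only
decoys, high-information JASPAR motifs, TF annotation table, and
initial/reference expression TSVs — with full ground truth recorded
(planted sites, true Kd, perturbed TFs, peripheral TFs).

Default shape: 30 TFs, 60 genes, 1 kb promoters, 16 bp motifs with one
dominant base per position (planted consensus occurrences score exactly
Sp = 1). Regulator slots are dealt from a balanced pool so every
connected TF regulates a comparable number of genes (2–3 sites per
regulator, at most 2 regulators per gene; ~10% of genes instead carry 4
sites of a single TF to exercise the super-enhancer regime; some
gene-body regions carry a planted repressive site). Motif width 16
matters: in ~60 kb of random promoter sequence the best chance window
for a random 16-mer matrix stays near Sp ≈ 0.8, which is inert at any
realistic Kd; shorter motifs produce chance near-consensus windows that
act as real sites.

Two TFs are generated *peripheral*: they have motifs and expression but
no planted sites, their genes receive no regulators, and their initial
expression is scaled to 0.02 — the analogue of the many motif-database
TFs with no open-chromatin targets in a given cell state. They give
perturbation experiments a guaranteed-inert control.

The initial expression table plays the role of measured RNA-seq input: a
log-normal draw (median 1, sigma 0.5) in units of the degradation
Michaelis constant. The reference table is produced by the model itself:
forward simulation from the initial state over the fit horizon (5 steps)
under the ground-truth Kd — optionally with per-TF fold changes — times
multiplicative log-normal noise (sigma 0.05) emulating measurement
error. The reference is therefore exactly reachable by the model class;
given the no-fixed-point property above, reachability over the fit
horizon is the meaningful self-consistency requirement, and an optional
burn-in is available but off by default. Default kinetics a = 10,
kc = 1, d = 0.5 keep expression O(1) over the horizon and occupancy in
its Kd-sensitive regime.

Perturbation experiments target the most-expressed connected TFs
(`default_perturbation_targets`): a TF with near-zero concentration or
no sites binds nothing at any Kd, so its Kd is unidentifiable in
principle and perturbing it plants no recoverable signal.

What the generator does *not* emulate: real JASPAR matrices (information
content varies; widths 6–20), ChIP-Atlas signal tracks, sequencing-depth
dependent noise, genes outside the TF roster regulating TFs, TF
complexes and dimers, and the scale of real rosters (hundreds of TFs).
Passing tests on these fixtures show the machinery is correct and the
inference behaves as designed under the model's own assumptions; they do
not certify recovery rates on real tissues.

## Numerical choices

- `wrightomega` for the Lambert-W degradation (no overflow for large x);
  g(0) = 0 handled explicitly.
- Occupancy padding: absent site slots carry zero weight and contribute
  exactly zero terms, so vectorized and per-site evaluations agree to
  machine precision.
- Flux at r = 0 is exactly 0 (continuity limit of exp(-1/r)).
- Degenerate inputs: empty peak lists, genes on absent chromosomes,
  sequences shorter than a motif, and empty candidate sets all return
  empty results rather than erroring; malformed intervals and PFMs error
  with the offending record named.
- Determinism: same seed and configuration produce byte-identical files
  (fixture bundles, profile CSVs, fit outputs).

## Limitations

- The model excludes post-transcriptional and post-translational
  regulation, cell–cell communication, and chromatin-state change during
  simulation, by design.
- Kd identifiability requires expression: lowly expressed TFs and TFs
  without open-chromatin sites cannot be ranked, and 20 descent steps
  recover the *direction and ranking* of planted Kd changes, not their
  magnitude (a x100 perturbation typically fits as a 2–3x Kd shift under
  the short horizon).
- Co-regulation spreads blame: when a perturbed TF shares all its
  targets with another regulator, part of the signal is absorbed by the
  co-regulator's Kd.
- The gradient-descent protocol is fixed-step-count and has no
  convergence criterion; results at other step counts will differ.
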