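# Methods

This note documents the models, parameter choices, numerical decisions, and
known limitations of `cyrpipe`, in the order the pipeline runs them.

## Sequence screen

Homology detection is pairwise alignment against a labeled reference panel,
not a profile/HMM search: it keeps the artifact self-contained and the panel
is an explicit, swappable input. Scoring is BLOSUM62 with affine gaps — a
gap of length L costs `gap_open + gap_extend * L` (defaults 11 and 1) — in
global mode with free end gaps, so N/C-terminal extensions are not
penalized. Traceback ties are resolved by taking the aligner's first optimal
alignment, which is deterministic for a fixed Biopython version; motif
positions are therefore reproducible run to run.

Percent identity is computed over the alignment's *core columns*: terminal
overhangs are stripped and internal gap columns count in the denominator.
For indel-free homolog pairs this equals the usual matches-over-aligned-
columns definition; for chance alignments of unrelated sequences, which
inflate their match count with cheap internal gaps, it is strictly lower.
Measured on 500 random 250-mers against the default panel, no unrelated
sequence reaches the default thresholds (25% identity at 0.6 reference
coverage; the worst case with adequate coverage was 21.8%), while planted
homologs at up to 0.3 substitutions/site stay above 55%. Both thresholds are
CLI flags.

Functional positions live in a named numbering system on each reference
(`ReferenceMap.numbering_label`), e.g. mature-bacteriorhodopsin numbering
(acceptor = residue 85) or plain scaffold coordinates for synthetic panels;
the convention is metadata and never inferred. A reference position that
aligns to a gap is reported as `-` with a warning, not an error, because a
missing donor is itself diagnostic (inward pumps and sensors lack one).

The function rule table is ordered, explicit, and total: (1) no Schiff-base
lysine → nonfunctional opsin; (2) DTD/DTE → outward H⁺ pump; (3) NDQ → Na⁺
pump; (4) NTQ/TSD → inward Cl⁻ pump; (5) acidic acceptor without a
carboxylic donor → inward H⁺ pump (the xenorhodopsin-like case); (6)
anything else → sensor/unknown. Proton-pump rules precede the ion-pump rules
because the clade of interest is H⁺-pumping; the table is a configurable
argument. Note that a DTD motif does not strictly guarantee proton pumping
(weakly active members may transport other ions); the label records the
motif-based expectation.

## Trees, clade assignment, habitat table

Maximum-likelihood tree building is deliberately replaced by neighbor
joining on p-distances with classical column-bootstrap supports: clade
assignment depends on clade *separation*, not branch-length optimality, and
NJ is provably consistent on additive distances (property-tested against
four-point-condition oracles). An externally computed newick tree can be
supplied to the `assign` subcommand to bypass the internal builder.

The multiple alignment is reference-anchored: every sequence is aligned
pairwise to one anchor and the rows are stacked on the anchor's columns,
dropping insertions relative to the anchor. Stacking uses its own scoring
(gap 20/2, end gaps penalized) because every stacked sequence is a
full-length homolog: with the permissive screening scheme, chance
off-diagonal similarity between distant clades can mis-register a sequence
against the anchor and inflate its within-clade distances severalfold.
Anchor stacking is adequate for indel-light data; for indel-rich real data a
proper progressive MSA upstream is recommended (known limitation).

p-distances are mismatch fractions over gap-free shared columns; a pair with
no shared columns is an error naming the pair. The Poisson correction
−ln(1−p) is available for tree building. Negative NJ branch lengths are
clamped to zero and the total deficit logged. Bootstrap: columns resampled
with replacement, support = percentage of replicate trees containing the
edge's bipartition; rows are sorted by label first so supports are invariant
to input order; the default 100 replicates matches common practice for this
kind of survey.

A query is assigned to the clade of its nearest reference (corrected
distance) only if three checks pass:

1. **No tie** — if the nearest distance is shared (within 1e-9) by
   references from two clades, the query stays unassigned.
2. **Distance gate** — the nearest-reference distance must not exceed
   1.5 × the clade's reference diameter (max pairwise reference distance)
   plus 0.02. With few clades in a tree, an unrelated long-branch sequence
   necessarily falls inside some clade's complement, where no topological
   criterion can reject it; its distance gives it away.
3. **Monophyly with support** — the query must fall inside the maximal
   monophyletic group containing all of the clade's references and none of
   any other clade's, and that group's subtending edge must have bootstrap
   support ≥ 50 (mirroring the usual display threshold). The *maximal* group
   is used rather than the minimal spanning subtree of the references
   because references rarely span every internal branch of their clade; the
   minimal subtree would exclude genuine members attached between reference
   branches. Edges without a support value pass, so the check degrades
   gracefully on un-bootstrapped trees.

The habitat table counts genes per clade and rhodopsin-possessing genomes
per habitat (marine / freshwater / saline / NA; "high salinity" maps to
Saline), stratified by genomic subclade (A–G, NA). Row and column sum
invariants hold by construction and are asserted in tests. Subclade labels
are consumed as input metadata; no species tree is built here.

## Photocycle model and fits

The scheme is the minimal irreversible chain K → M → O → ground with
initial condition K(0) = f (the flash-excited fraction, default 0.3). No
back-reactions or additional intermediates are modeled because none are
resolved for this pigment. Populations are evaluated in closed form via
divided differences of e^{−kt}: M = −f·k1·dd1(k1,k2), O = f·k1·k2·
dd2(k1,k2,k3), computed through `expm1` with nodes sorted so the difference
arguments are non-positive. This reduces to the textbook partial-fraction
form for distinct rates and to the t·e^{−kt} / t²·e^{−kt} confluent limits
for (near-)equal rates (tie threshold 1e-9 relative) without case analysis,
and agrees with a high-order Runge–Kutta integration to ≲1e-13 across random
rate triples in [1e-4, 10] ms⁻¹. Mass is conserved exactly because the
recovered-ground population is computed as f − K − M − O.

Spectral bands are Gaussians in wavelength (a transparency-over-physics
simplification; real bands are closer to Gaussian in wavenumber): ground
550/40 nm, K 620/40 (amplitude 0.8), M 405/30 (1.0), O 645/40 (0.9),
relative extinctions chosen at order unity. ΔA(λ,t) is the
population-weighted band sum minus the ground band weighted by the cycling
fraction, so it relaxes to zero on completion. Light/dark adaptation is
ignored (one ground state): the pigment's retinal is predominantly all-trans
in both conditions with identical λmax. All ΔA amplitudes scale linearly in
f, so inferred quantities are rates, timings, and peak positions — never
absolute amplitudes.

Rate defaults: k2 = 0.016 ms⁻¹ is the published pH 7.0 M-decay constant and
serves as simulation truth; k1 = 2 ms⁻¹ and k3 = 0.05 ms⁻¹ are not published
and are modeling defaults chosen so M appears within ~2 ms and the cycle
completes within ~300 ms, consistent with the reported observation windows.
With these defaults the 550-nm bleach recovers ≥ 95% across the 240–360 ms
window (tested property).

The M-decay fit is A·e^{−kt} + c on the 405-nm trace restricted to times
after its extremum, nonlinear least squares with eight log-spaced initial
rates in [1e-4, 10] ms⁻¹ and k bounded positive; best SSE wins; a trace with
no decay phase after its extremum is an error. The global fit is variable
projection: for a candidate τ set the decay-associated spectra (DAS) are the
linear least-squares solution, and the nonlinear search runs over log-τ only
(eight jittered log-spaced starts, seeded; SSE tolerance 1e-10; duplicate τ
within 1e-6 relative are rejected as rank-deficient and restarted, then
errored). Components are labeled K/M/O by a one-to-one assignment minimizing
total distance between each DAS's positive-peak wavelength and the
configured band centers (620/405/645 nm) — one-to-one matters because the
slowest component's DAS peaks at the recovering ground band (550 nm), not at
the O band. The pyranine proton trace is −coupling·[M](t) under 1:1
release/uptake stoichiometry: bulk acidification on M formation, uptake on
M decay. The per-pH M-decay table reports the trend but never enforces
monotonicity; a single pH is allowed (one-row table).

## pKa titration

Occupancy is the single-site Henderson–Hasselbalch form 1/(1+10^{pKa−pH}),
Hill slope fixed at 1; multi-site fitting is out of scope. The tracking
wavelength defaults to the one with maximal absorbance range across the
series (the acid and alkaline transitions shift different bands, so no
single fixed wavelength suits both); a fixed wavelength may be requested. A
series whose lightly smoothed tracking curve spans less than 3× the noise
scale is rejected as "no transition" — the smoothing (window 3–5) prevents
noise extremes at the max-range wavelength from mimicking a transition.

Censoring: an estimate within 0.5 pH units of a grid edge (boundary
inclusive) is flagged, and the fit reports a bound placed 1.0 unit inside
that edge — a midpoint that close to the boundary is not reliably bracketed.
On a grid starting at pH 1.00 this reproduces the "< 2.0" reporting style
for a strongly acid-shifted proton acceptor. Uncensored fits report the
estimate with its covariance-based standard error.

## Synthetic data: what it does and does not emulate

Sequences: a uniform-random scaffold (250 residues) carries the
functional-site map (default: mature-BR positions 85/89/96/194/204/212/216;
an N2098R map with 74/78/85/182/192/200/204 is provided). Each clade
descends from its own founder — the scaffold mutated at 0.5
substitutions/site (`clade_separation`) — and members are substitution-only
mutants of the founder at the template's divergence (default 0.1, max 0.6),
with motif and Schiff sites protected. Substitution-only evolution keeps
site positions exact; indel robustness is exercised by an `indel_stress`
option inserting ≤5-residue loops ≥10 residues away from any mapped site.
Two negative classes exist: uniform-random decoys with the Schiff position
forced to non-lysine (non-homologs), and optional "decoy" templates
(homologs lacking the lysine). Habitat labels are drawn per template; the
CyR-like default puts zero mass on marine — a generator default reflecting
the clade's described distribution, not a claim about real genomes.

The generator does not emulate realistic proteome composition, synteny,
nucleotide-level evolution, site-rate heterogeneity, or alignment ambiguity;
passing recovery tests therefore demonstrates correctness of the inference
machinery under the declared generative model, not performance on real
survey data.

Spectra: flash matrices are the forward model plus i.i.d. Gaussian noise on
the instrument grids (370–700 nm step 5; 100 log-spaced times in 0.01–977
ms); titration series mix protonated/deprotonated species bands by occupancy
over 250–750 nm, with a pH-independent 280-nm protein band for realism.
Generator-default titration truths are 10.7 (alkaline, the published
Schiff-base midpoint) and 1.5 (acid side, a spec-level choice below the
bracketable range of a pH 1.00 grid so that the censored path is exercised).

Determinism: every generator is a pure function of (arguments, seed); a
master seed spawns per-component substreams via `numpy.random.SeedSequence`.
A fixed 154-genome record fixture reconstructs the published survey's
marginal totals (56 genes: 3/1/15/24/13 across clades; 42 possessing
genomes: 2 marine / 29 freshwater / 9 saline / 2 NA; diox1 in 152/154); its
per-subclade placement is arbitrary plumbing and only the totals are
meaningful.

## Problem sizes

Default test and demo sizes are desk-scale by design: ~10–60 proteins per
screen, 10–30 taxa per tree with 100 bootstrap replicates, 67×100 flash
matrices, 17–21-point titration series, and 20–50 seeds per recovery
experiment. These sizes give stable seed-averaged estimates (recovery errors
well inside the asserted tolerances) while keeping the full suite fast.

## Known limitations

- Real survey counts cannot be reproduced: the original genome set and
  search tool/thresholds are not part of this package's inputs, and the
  reference panel for real use is user-supplied.
- Anchor stacking degrades on indel-rich or highly divergent sets; use an
  external MSA/tree for such data.
- The pH dependence of the M-decay rate is reported per dataset; no
  functional form is fitted because none is established for this pigment.
- Absolute spectroscopic amplitudes are not meaningful (linear in the
  excited fraction); only rates, timings, and peak positions are inferred.
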