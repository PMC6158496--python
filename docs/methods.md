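# Methods

`thetaknot` mechanizes a topological analysis of DNA knotting in stalled
replication intermediates (RIs).  A partially replicated circular DNA
molecule is a **theta-curve**: a spatial embedding of the graph with two
vertices (the replication forks) and three edges (the two freshly
replicated sister duplexes, `SISTER_A`/`SISTER_B`, and the unreplicated
portion, `UNREPLICATED`), studied up to ambient isotopy.  A type-II
topoisomerase (Topo IV in *E. coli*) acts by a single duplex–duplex
passage, modelled as one **crossing change** on a diagram.  The package
asks: which knotted theta-curves can one or two such passages create
from the unknotted intermediate, and what knots appear in the freshly
replicated portion (the **FR knot**, the constituent cycle formed by the
two sister edges, observed experimentally after restriction digestion of
the unreplicated portion)?

## Diagram calculus

Diagrams are combinatorial planar maps: crossings carry four arc-end
slots in counterclockwise cyclic order with a flag marking the over
strand (opposite slot pair), trivalent vertices carry three slots, arcs
pair slots, and crossingless closed components are kept as labelled
loops.  Planarity is validated by tracing faces from the rotation system
("arrive at slot *k*, depart at slot *k*+1") and requiring V − E + F = 2
per connected component.  Canonical renumbering is breadth-first from
the lowest-id vertex (else crossing) and defines syntactic equality; a
rotation-invariant traversal key (minimized over traversal roots and
entry slots, with over flags stored relative to the entry slot because
rotating a crossing's slot labels by one flips the flag) provides
isomorphism-invariant deduplication for searches.

Moves I–III are the classical Reidemeister moves.  For trivalent
vertices the calculus adds move IV (a strand slides across a vertex,
exchanging its two crossings with two of the edges for one crossing with
the third edge, so the crossing count changes by ±1) and move V (two
adjacent edges at a vertex twist past each other, changing the count by
±1).  These deltas follow the standard spatial-graph calculus.  Each
move application is a local surgery on the map; all of them were
derived once from explicit coordinate pictures (the move-IV and move-III
rewirings are the delicate ones — move III reduces to swapping the two
external arc-ends of each of the three strands involved) and are
continuously checked in the test suite by validating planarity and
invariance of the fingerprints below after every applied move.

`simplify` performs a deterministic crossing-minimizing search: reducing
moves (R1−, R2−, R4−, R5−) to a fixed point, then breadth-first search
over R3/R4/R5 detours with a bounded transient R2+ slack (defaults:
depth 8, slack 2, 4000 states), preferring fewer crossings and breaking
ties by canonical form.  It is a budgeted search, not a decision
procedure; returned move traces replay bit-exactly.

## Invariants

**Knots.**  The Kauffman bracket is computed as the full 2ⁿ smoothing
state sum with loop value −A² − A⁻²; the classification fingerprint is
the writhe-normalized bracket f(D) = (−A³)^(−w)⟨D⟩ together with the
knot determinant.  The determinant is computed from the Goeritz matrix
of a checkerboard colouring (exact integer arithmetic); the test suite
cross-checks it against an independent evaluation of the bracket at a
primitive 8th root of unity.  A structural consistency check ties the
sign convention for crossings to the smoothing convention: f(D) of a
knot must be a polynomial in A⁴, which fails if either convention is
mirrored relative to the other.

**Theta-curves.**  The classifier is a Yamada-type state sum: each
crossing expands into the A-smoothing (weight A), the B-smoothing
(weight A⁻¹) and the flat 4-valent vertex (weight 1), and the resulting
flat graph G is evaluated by its integer flow polynomial F(G; k) at
k = 2 − A − A⁻¹ (computed by contraction–deletion with memoization; a
free circle contributes c = 1 − A − A⁻¹).  With these constants the sum
is invariant under moves II–V and picks up a unit ±Aⁿ under move I and
vertex twists; the declared normalization (divide by ±Aⁿ so the lowest
exponent is 0 with positive lowest coefficient) removes the unit.  Two
derivations fix the constants: invariance under move II requires the
vertex-coefficient identity A + A⁻¹ + c − 1 = 0 once the flat "H"
tangle is rewritten via contraction–deletion as (4-valent vertex) −
(parallel smoothing), and a vertex twist then multiplies the sum by
−A^(∓1) while a kink multiplies it by −A^(±2).  The full fingerprint of
a theta-curve is the normalized polynomial plus the sorted multiset of
its three constituent-knot fingerprints; the mirror image corresponds to
A → A⁻¹ throughout.  Fingerprint equality is necessary but not
sufficient for equivalence, so positive identifications of achirality or
equivalence come from a bounded breadth-first move search that returns
an explicit move sequence; inequality of fingerprints certifies
distinctness outright.  Every invariance claim is additionally verified
computationally (seeded random move walks, and agreement with naive
state-sum enumerations implemented independently in the tests).

## Conventions: signs, chirality, names

A crossing is positive when the over-strand direction is the
counterclockwise quarter-turn of the under-strand direction; with the
A-smoothing convention used here this makes the all-positive trefoil the
one whose normalized bracket lies in negative powers of A.  For chiral
knots the **barred** name denotes the right-handed form, defined as the
chirality whose reduced alternating diagram has positive writhe; thus
`3_1bar` is the all-positive trefoil, matching the usage for knots
isolated from stalled intermediates, and unbarred names are the
left-handed forms.  `4_1` and `6_3` are achiral (certified by explicit
move sequences to their mirrors).

Theta edges are oriented as the boundary cycle of the replication
bubble: `SISTER_A` and `UNREPLICATED` from the lower fork to the higher,
`SISTER_B` back.  Under this (antiparallel-sister) convention the
left-handed geometric winding of the sisters gives precatenane crossings
of **positive** sign, which is the stalled-RI convention: the package
default `precatenane_sign=+1` produces the right-handed knotted series.

## The catalog

All diagrams are generated programmatically.  Every prime knot with at
most seven crossings is 2-bridge, so the knot half of the catalog (both
chiralities of 3₁ … 7₇ plus the unknot, 27 entries) is built exactly
from positive continued-fraction rational-tangle diagrams; identities
are pinned by the (crossing number, determinant) pair, which is
injective in this range, and fingerprints are checked pairwise distinct.
The theta-curve half contains the trivial curve and the curves the
passage model names: `theta3_1` and `theta4_1` (the one- and two-winding
products; the curve names are forced, these being the unique 3- and
4-crossing prime curves), `theta5_6bar` (the three-winding product,
whose FR constituent is `5_2bar`; its mirror is `theta5_6`), and a
**synthetic stand-in** for the remaining 5-crossing unknotting-number-
one curve, labelled `theta5_7`: a curve found by deterministic search
over single crossing changes on expanded trivial-theta diagrams,
Yamada-distinct from every other entry and mirror.  The published
curve table itself is not reproducible here, so curves beyond this set
(including 6- and 7-crossing products) are reported `UNCLASSIFIED` with
the crossing bound reached.  `verify_catalog` is the release gate:
diagram validity, fingerprint recomputability and pairwise separation,
constituent identities, unknotting certificates, and the
single-nontrivial-constituent pattern (reported, not enforced).

## The replication-intermediate model

`build_ri(p, s)` lays the molecule out as the idealized hairpin: the two
sisters leave fork 0, wind through a 2-strand twist region of *p*
same-sign crossings, turn at the apex and return to fork 1; the
unreplicated edge closes the bubble and carries *s* curl crossings
standing for the plectonemic supercoils (they are removable by
simplification, exactly as unreplicated supercoiling cannot knot the
curve; the curl handedness is a parameter since the printed geometry
does not fix it, default negative).  With no passage the diagram
simplifies to the trivial curve for every *p* and *s* — precatenanes
alone do not knot.

The thermal-fluctuation overlap is a deterministic cancelling
two-crossing clasp (an R2 move) inserted between a fork-adjacent sister
segment and one of the two returning-arm strands; when the engaged arm
strand is the far one, the finger first passes through the near strand,
leaving an extra cancelling pair.  A passage is a crossing change at one
of the two clasp crossings.  Empirically — and this is a structural
finding of the mechanization — the two crossings of one overlap trap
*consecutive* winding counts: an overlap traps the pair (w, w+1) where
w is odd for intra-sister engagements and even for inter-sister ones
(intra overlaps with nothing trapped exist as the special closely-spaced
case).  The route parameter (`upper`/`lower`) selects the crossing, and
`simulate_passage` defaults to the route trapping exactly the configured
winding count.  Products are the twist family: trapping w windings
yields the (w+2)-crossing twist-knot theta-curve whose FR knot is the
right-handed (w+2)-crossing twist knot — 3₁bar, 4₁, 5₂bar, 6₁bar, … —
and the classified outcome sets of the intra- and inter-sister pathways
coincide (the headline convergence).  The two theta4_1 products (intra-
and inter-formed) carry identical fingerprints here, so the package
reports them as the same classified curve; a finer invariant might
separate them, but none of the shipped analyses depends on it.
`mirror_prediction` maps a result to its mirror classes, the expected
outcome for positively supercoiled (actively replicating) molecules.

For the 6₂bar FR knot, which is not a twist-family product of a single
passage, the four pathway configurations are constructed from the
crossing-change spectrum of the minimal `6_2bar` diagram: its six
crossings yield exactly the starting knots {unknot, 3_1bar, 4_1} under a
single change.  Each pre-change knot diagram is closed into a
theta-curve by splicing the two fork vertices and the unreplicated edge
into a face (a search over splice positions finds one identifying to
the required starting curve), and the recorded change then produces the
6₂bar FR knot.  Pathways (iii) and (iv) share the second passage but
differ in the first-passage provenance of the starting theta4_1.

## Unknotting numbers

`unknotting_number` is iterative-deepening search over crossing changes
interleaved with simplification, on the simplified diagram and on
expansions by up to two crossing-increasing moves (a minimal diagram
need not expose an unknotting crossing; for the shipped catalog the
minimal diagrams do).  Upper bounds come with replayable certificates;
lower bounds are fingerprint nontriviality (≥ 1) plus exhaustive
depth-k failure, reported as search-relative.  All knotted catalog
curves have u = 1 — they arise from the trivial curve by one passage by
construction, and their nontrivial fingerprints exclude 0.

## Problem sizes, determinism, limitations

State sums are exponential (2ⁿ bracket, 3ⁿ Yamada) and capped at 14
crossings; identification simplifies first, and theta fingerprints
simplify whenever the diagram exceeds 9 crossings.  All searches are
deterministic: move enumeration is sorted, ties break on canonical
forms, and every stochastic element (perturbation streams) is seeded
and derandomized in tests.  The analyses run at desk scale: outcome
tables to three windings, perturbation checks with 200 seeded sequences
of up to six moves per catalog entry, equivalence searches capped at a
few tens of thousands of states.

What the synthetic stage does *not* model: passage kinetics, enzyme
preference or rates; plectoneme mechanics (the replicated region is the
drawn planar bend, not a higher-order superhelix); composite curves and
links; curves beyond seven crossings (unnamed by design); and
thermal fluctuation as a stochastic process — the overlap is the
deterministic clasp the geometry dictates, so passing tests certify the
topology of the pathways, not their statistics.  Fingerprint equality
is not a proof of equivalence (positive certificates come only from
bounded move search), and unknotting lower bounds beyond 1 are
search-relative, never proofs.
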