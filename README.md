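# thetaknot

A planar-diagram calculus for knots and **theta-curves**, built to
analyse how DNA knots form in partially replicated DNA molecules.

A replication intermediate (RI) — a circular DNA molecule caught partway
through replication — is topologically a theta-curve: two vertices at
the replication forks, joined by the two freshly replicated sister
duplexes and the unreplicated portion.  In stalled intermediates the
sisters wind around each other (*precatenanes*), and type-II
topoisomerases, which act by passing one duplex segment through
another, occasionally knot the molecule.  The knots recovered from
cells — right-handed 3₁, achiral 4₁, right-handed 5₂ and 6₂ in the
freshly replicated portion — are a fingerprint of the three-dimensional
arrangement of the replicating molecule.  This package mechanizes that
inference: it represents RIs as combinatorial theta-curve diagrams,
models a topoisomerase passage as a crossing change, identifies the
products with polynomial invariants against an embedded catalog, and
shows that intra-sister and inter-sister passages produce the same
ladder of knotted theta-curves, with the trapped precatenane windings
setting the knot complexity.

It is aimed at DNA-topology and computational-biology researchers who
want reproducible, certificate-backed versions of these by-hand
topological arguments.

## The model in brief

* **Curves.**  A theta-curve θ has edges {A, B, U} (sisters and
  unreplicated); each pair of edges is a *constituent knot*, and the
  A∪B constituent is the **FR knot** observed after digesting U.
* **Moves.**  Diagrams are equivalent under Reidemeister moves I–V
  (I–III classical; IV slides a strand across a fork vertex, V twists
  two edges at a vertex).  A topoisomerase passage is a crossing
  change — the only operation that alters the topology; it changes the
  signed writhe by ±2.
* **Invariants.**  Knots: writhe-normalized Kauffman bracket
  f(D) = (−A³)^(−w)⟨D⟩ plus the determinant.  Theta-curves: a
  Yamada-type state sum (crossings expand into two smoothings and a
  flat vertex; flat graphs evaluate by the flow polynomial at
  k = 2 − A − A⁻¹), normalized up to ±Aⁿ, plus the constituent
  multiset.
* **Passages.**  `simulate_passage` builds the idealized wound RI,
  inserts a thermal-fluctuation overlap (a cancelling clasp) at an
  intra- or inter-sister locus, changes one of its two crossings, and
  identifies the product.  Trapping w windings yields the
  (w+2)-crossing twist-knot theta-curve; its FR knot is the
  right-handed twist knot with w+2 crossings.
* **Unknotting number** u(θ): the least number of crossing changes to
  the trivial curve, computed by bounded search with replayable
  certificates.

## Worked example

One passage between segments of the same sister duplex, trapping a
single precatenane winding:

```
$ thetaknot simulate -w 1 --locus intra
{
  "provenance": { "tool": "thetaknot", "version": "0.1.0", ... },
  "theta": "theta3_1",
  "fr_knot": "3_1bar",
  "trapped_windings": 1,
  "product_crossings": 3,
  ...
}
```

The product is the 3-crossing knotted theta-curve `theta3_1`; cutting
the unreplicated edge leaves `3_1bar`, the right-handed trefoil — the
knot in the first electrophoretic band of the digested intermediates.
The full ladder, for both pathways (`analysis/02_single_passage.py` or
`thetaknot table --max-windings 3`), includes rows such as:

```
  locus  route trapped theta_name   fr_knot  chirality classified
INTRA_A  upper       1 theta3_1      3_1bar  standard  True
INTRA_A  lower       2 theta4_1      4_1     standard  True
  INTER  lower       3 theta5_6bar   5_2bar  mirror    True
  INTER  upper       2 theta4_1      4_1     standard  True
```

The classified product sets of the intra- and inter-sister pathways are
identical — `{theta0_1, theta3_1, theta4_1, theta5_6bar}` at up to
three trapped windings — which is the model's central claim: the
enzyme acts locally and cannot tell sisters apart, and both pathways
require precatenated sisters.  The FR-knot series 3₁bar, 4₁, 5₂bar, …
is right-handed or achiral, as observed; for positively supercoiled
(actively replicating) molecules `mirror_prediction` returns the mirror
classes.  `analysis/04_second_passage.py` reproduces the four pathway
configurations that explain the remaining observed knot, `6_2bar`, as a
passage on an unknotted, `theta3_1` or `theta4_1` intermediate.

Unknotting numbers come with certificates:

```
$ thetaknot catalog export --dir cat && thetaknot unknot cat/theta3_1.tdg
{ ..., "u_upper": 1, "u_lower": 1, "value": 1, ... }
```

## Layout

```
src/thetaknot/     library: diagram core, moves, state sums, catalog,
                   RI model, unknotting search, fixtures, CLI
analysis/          numbered narrative drivers writing results/
tests/             pytest suite (unit, property and acceptance tests)
scripts/           acceptance script
docs/methods.md    model, conventions, derivations, limitations
```
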