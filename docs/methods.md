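# Methods

## Model

`sdmm` treats a patient's post-surgical anatomy as a *derived* quantity:
a reference model (the basic anatomy, BA) plus an ordered list of
machine-readable surgery deltas. Nothing about the patient's current
anatomy is ever stored directly; every state is recomputed by folding the
deltas over the BA, which makes the representation trivially transferable
(only the markup has to move between institutions) and auditable (every
state change is attributable to a dated surgical step).

### Basic anatomy

The BA has three layers:

1. **Hierarchy** — anatomical structures form one tree per functional
   organ class (`Arterial`, `Venous`, `Portal`, `Liver`, `Biliary`,
   `Pancreatic`, `Intestine`). The parent relation encodes *origination*:
   where on its parent a structure arises. It drives rendering and
   detachment bookkeeping, not function.
2. **Geometry** — every structure is an abstract tube parameterized by
   arc length `[0, length_mm)`, half-open, 0-based, in millimetres.
   Offset 0 is the proximal/inflow end. Diameters are carried but not
   used geometrically.
3. **Function** — directed *natural links* `(from, from_offset) →
   (to, to_offset)` with a relation (`luminal`, `arterial`, `venous`,
   `portal`, `biliary`, `pancreatic`). Direction is physiological flow.
   Links may form cycles; all traversals use visited-sets. When a
   document omits link offsets, the defaults are the distal end of the
   source and the proximal end of the target.

Named landmarks (`ligament_of_treitz`, `esophageal_inlet`,
`rectum_distal`, ...) are first-class so that distance queries can be
phrased clinically.

One deliberately schematic classification: the superior mesenteric vein
sits in the `Venous` tree (under the inferior vena cava) so that
portal-confluence surgery documents as a venous-class resection, while its
actual drainage into the portal vein is modelled — correctly — by a
portal-relation natural link. Hierarchy is origination; links are
function.

### Surgery deltas

A patient record holds dated surgery events; each event holds numbered
steps with verbatim narrative text plus zero or more annotations:

- **Resection** — removal of a whole structure or a half-open interval
  `[start, end)` of it.
- **Reconstruction** — an artificial link (anastomosis) joining two
  points, with a kind label, a relation, and an intrinsic length that
  defaults to 0 (an anastomosis joins two points).
- **Biometric override** — a measured length or diameter replacing the
  BA's textbook default from that event onward.

Only the annotations are needed to rebuild the model (`extract_deltas` /
`reconstruct_from_deltas`); the narrative is for humans and is preserved
byte-for-byte (CDATA on write) because surgical documentation is legally
sensitive.

## State derivation

States are immutable; each event application produces a new state,
atomically (an error leaves the input untouched). Annotations apply
sequentially in document order. The shipped cases and the generator
author each step's annotations in biometric → resection → reconstruction
order, the typical surgical order.

**Residual tissue** per structure is a sorted, disjoint, maximal list of
half-open intervals. A structure absent from the map is fully present,
so the birth state equals the BA by construction. Point membership
("does an anastomosis sit on residual tissue?") uses the *closure* of the
intervals so an anastomosis may sit exactly on a cut end — the typical
case.

**Exact arithmetic.** All interval endpoints are `fractions.Fraction`.
The conservation law

    residual length + cumulative resected length = effective length

therefore holds *exactly* (a rational zero, not a float tolerance) at
every timeline point, including under proportional rescaling.

**Biometric length overrides** rescale the structure's entire coordinate
system: residual intervals, the accumulated resected length and active
artificial-link offsets scale by `new/old`, preserving the topology of
prior resections; BA-defined offsets (attachments, natural-link
endpoints, landmarks) are interpreted through the current scale factor.
Later annotations are expressed in current (effective) coordinates — a
surgeon measures the anatomy as it is.

**Conflicts.** Resecting already-resected tissue is an error by default;
with `clip_overlaps` the request is intersected with residual tissue and
a warning logged. A resection that would strand an active anastomosis,
or a reconstruction onto resected tissue, raises a dangling-anastomosis
error. Whole-structure resection of a structure with children marks
children whose attachment point is lost as *detached* — reported in the
state, never silently removed.

**Surgical load** has no canonical formula; this package operationalizes
it as, per organ class: total resected length (mm), number of whole
structures removed, and number of active artificial links, attributed to
a class via the link's relation (an anastomosis may join two classes).
These are non-decreasing along every timeline the fixtures and generator
produce; a shrinking length override on an already-resected structure
could in principle lower the resected total, so the generator only
overrides lengths of untouched structures.

## Queries

Queries run on a weighted *segment graph*: nodes are points of interest
(link endpoints, query points, interval boundaries) on residual tissue;
edges are residual stretches between consecutive points on one structure
(weight = arc length, direction proximal → distal) plus links of the
queried relation (weight = intrinsic length, flow direction). An
`undirected` flag relaxes direction for anatomical distance.

`path_distance` is Dijkstra with a deterministic tie-break: among
equal-length paths, the lexicographically smallest structure-id sequence.
`supplying_vessels` is reverse reachability from the target structure,
restricted to the organ class conventionally carrying the relation.

The test suite checks every query operation against an independent
brute-force oracle that cuts all structures into 1-mm cells on the
integer grid and runs plain Dijkstra/BFS on the explicit cell graph.
All fixture and generated coordinates are integer millimetres, so
reachability must agree exactly and distances to within 1 mm (they agree
to 0 mm in practice).

## Rendering

Layout is schematic: each structure is a straight polyline starting at
its parent's attachment point, with a direction derived from a SHA-256
hash of the structure id (stable across runs and machines). Arc length
is preserved, so measuring along a rendered structure is meaningful;
the 3D arrangement is not anatomically metric. Styling: residual tissue
solid in a fixed organ-class palette, resected intervals dotted, and
artificial links bold green — green is reserved for reconstructions.
Exactly one primitive per maximal residual interval, per maximal
resected interval, and per artificial link.

Exports: SVG 1.1 (orthographic XY projection, dotted via
`stroke-dasharray`), Wavefront OBJ (`l` polylines), glTF 2.0 (JSON, line
strips, base64 data-URI buffer). Floats are formatted with 3 decimals,
making all exports byte-deterministic. The timeline SVG divides the axis
into decades of patient age (one gridline per completed decade), flags
each surgery at its date, and shows the birth-state schematic on the left
and the cumulative state on the right.

## Synthetic cases

The packaged digestive BA uses textbook default biometrics (esophagus
250 mm, stomach 250 mm, duodenum 260 mm, jejunum 2000 mm, ileum 3000 mm —
small intestine ≈ 5.3 m including the duodenum; colon segments, biliary
tree, pancreas, splanchnic arteries, caval/portal veins). The named
structure set `small_intestine` is duodenum + jejunum + ileum.

P1 (appendectomy; two adhesiolysis-only relaparotomies; left
hemicolectomy; esophagectomy with gastric sleeve and
gastroesophagostomy) and P2 (cholecystectomy; ileocecal resection; ileum
segment resection; left hemicolectomy; duodenum-preserving pancreatic
head resection with partial superior-mesenteric-vein resection and
venous reconstruction) are concretizations of those named procedures;
the exact intervals and anastomosis positions are clinical choices
commented in `fixtures.py`, not measured data.

The random-case generator (`CaseSpec`: seed, number of surgeries 0–10,
per-event annotation probabilities, interval-width range 20–400 mm)
simulates the timeline forward while drawing annotations, so every
generated record replays without conflicts. It emulates realistic
surgical *bookkeeping* — it does not emulate clinical plausibility of
procedure combinations, narrative content, or correlated re-operations.
Passing property tests on generated cases therefore demonstrates the
engine's algebraic guarantees (conservation, delta sufficiency,
round-trips, oracle equivalence), not clinical validity on real records.

## Problem sizes and numerics

Property suites run on the two fixture cases plus seeded generated
cohorts: 100 cases for conservation and delta-transfer equivalence, 50
for query-oracle equivalence, 200 for serialization round-trips — sizes
at which the whole suite completes in well under a minute while touching
every annotation kind many times. Interval arithmetic is exact rational;
floats appear only at API boundaries (lengths in query results, export
coordinates). XML floats are written in shortest round-trip form, so
load → write → load is an identity.

## Known limitations

- Structures are 1-D tubes; sleeve resections, wedge resections and
  volumetric organs are approximated by interval resections plus
  diameter overrides.
- Detachment tracks origination only; a detached structure's own tissue
  and links remain active.
- Surgical-load monotonicity is guaranteed only under the fixture and
  generator conventions described above.
- The layout is an original deterministic scheme optimized for
  reproducibility, not for visual fidelity to any atlas.
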