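# sdmm — markup-based life-spanning surgical documentation

Patients who undergo many abdominal operations accumulate a *surgical
load*: resected bowel, rerouted continuity, anastomoses. Classic
narrative operation notes describe procedures, not results, so answering
even elementary questions — *how long is the residual small intestine?
how far from the ligament of Treitz is that anastomosis?* — means
reading every report ever written for the patient.

`sdmm` models the alternative: a **basic anatomy** (BA) — organ-class
trees of tubular structures connected by directed functional *natural
links* — is modified by per-surgery **markup deltas** (resections,
reconstructions/anastomoses, biometric overrides) attached to the steps
of dated surgery reports. Every anatomical state is derived, never
stored: folding the deltas over the BA yields the patient's anatomy at
any date, the cumulative surgical-load timeline, functional path
queries, and deterministic schematic renderings (SVG / OBJ / glTF).
Each structure is an arc-length-parameterized tube `[0, L)` in mm;
residual tissue is kept as exact rational half-open intervals, so

    residual + resected = effective length

holds exactly at every timeline point. Only the markup needs to be
transferred to rebuild the model elsewhere (`extract_deltas` →
`reconstruct_from_deltas`).

The package ships a digestive BA (7 organ classes, esophagus-to-rectum
luminal chain, biliary tree, pancreas, splanchnic vessels), two fully
worked simulated patients (P1, P2, five surgeries each), a seeded
random-case generator, and a `sdmm` command line.

## Worked example

Patient P2: cholecystectomy, ileocecal resection, ileum segment
resection, left hemicolectomy, pancreatic head resection with partial
resection of the superior mesenteric vein.

```python
import sdmm
from sdmm import QueryPoint
from sdmm.fixtures import STRUCTURE_SETS

ba = sdmm.load_fixture_ba()
p2 = sdmm.load_fixture_record("P2")
tl = sdmm.compute_timeline(ba, p2)
state = tl.final_state

print(sdmm.residual_length(state, structure_ids=STRUCTURE_SETS["small_intestine"]))
# 4660.0        -> 4.66 m of small intestine remain (600 mm of ileum resected)

path = sdmm.path_distance(state,
                          QueryPoint.at_landmark("ligament_of_treitz"),
                          QueryPoint.at_landmark("rectum_distal"))
print(path.total_length_mm, path.links_crossed)
# 5300.0 ('jejunum->ileum', 'al_p2_ileo', 'al_p2_ileocol',
#         'ascending_colon->transverse_colon', 'al_p2_colo',
#         'sigmoid_colon->rectum')
# -> 5.30 m of residual gut from the duodenojejunal flexure to the anus,
#    crossing the ileoileostomy, the ileocolostomy and the colocolostomy

print(sdmm.supplying_vessels(state, "ileum"))
# ['abdominal_aorta', 'superior_mesenteric_artery']
```

The same answers from the shell:

```sh
sdmm query residual-length src/sdmm/data/basic_anatomy_digestive.xml \
     src/sdmm/data/case_p2.xml --structures set:small_intestine
# {"selection": "set:small_intestine", "residual_length_mm": 4660.0,
#  "as_of_date": "2020-06-18"}

sdmm timeline src/sdmm/data/basic_anatomy_digestive.xml \
     src/sdmm/data/case_p2.xml --out out/
# out/states.jsonl  out/surgical_load.csv  out/timeline.svg
```

`sdmm validate` checks documents against the shipped XML schemas and
model invariants (exit 0 clean, 1 violations, 2 parse errors), and
`sdmm render` exports a state scene or the decade-gridded timeline.

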