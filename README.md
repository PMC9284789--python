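# dtplan

Geometry-based dynamic-trajectory planning for C-arm linacs, with plan-QA
tooling. The package builds beam's-eye-view (BEV) target/OAR overlap cost
maps over gantry–table space, masks out collision and CT-scan-length
exclusion zones, finds gradient-constrained minimum-cost gantry–table and
collimator–gantry paths with an A* search, smooths and duplicates them into
deliverable trajectory sets, and evaluates plans via DVH endpoints (D_x%,
D_0.03cc, V_x, mean dose), Paddick conformity, the V95−V105 homogeneity
index, global gamma analysis, and machine-log accuracy statistics.
Everything is exercised on synthetic anthropomorphic-like phantoms — no
external data needed.

## Layout

| module | contents |
|---|---|
| `dtplan.synth` | synthetic phantoms (ellipsoids/cylinders), analytic dose distributions, lagged delivery logs |
| `dtplan.bev` | structure volumes, beam geometry/frames, divergent BEV projection, fractional overlap |
| `dtplan.collision` | analytic gantry-ring vs patient/table-envelope collision test, CT-length exclusion |
| `dtplan.costmap` | gantry–table overlap cost maps, collimator–gantry field-width maps, path recipes |
| `dtplan.pathfinding` | A* column search (zero heuristic → provably optimal), moving-average smoothing, split-field / 90° collimator-offset duplication, deliverability checks |
| `dtplan.metrics` | DVH, D_x%/D_cc/V_x endpoints, normalization rules, Paddick CI, HI95 |
| `dtplan.gamma` | global gamma index (default 2%/2 mm, 10% low-dose threshold) |
| `dtplan.logs` | delivery-log deviation/speed statistics (RMS, max, Pearson speed–deviation correlation) |
| `dtplan.io` / `dtplan.cli` | NIfTI+JSON volumes, CSV/JSON trajectories, YAML configs, CLI |

Defaults follow the published dynamic-trajectory protocol: control points
every 2° of gantry over a full rotation, a 3°/° table/collimator gradient
limit, a 10-point (~20°) moving-average smoothing window, a 2 cm collision
safety margin per component, and 2%/2 mm/10% gamma criteria.

Coordinate conventions (documented in `dtplan/bev.py`): patient frame x
lateral / y anterior / z superior, isocenter at the origin; gantry rotates
about z with the source above the patient at gantry 0; the table rotates
the patient about the vertical axis.

## CLI

```bash
dtplan synth-phantom --out phantom/ --spacing-mm 2
dtplan costmap    --config cfg.yaml --structures phantom/structures.json --out maps/ --plot
dtplan plan-paths --config cfg.yaml --structures phantom/structures.json --out plan/
dtplan metrics    --dose dose.nii.gz --structures phantom/structures.json --normalize --out metrics.json
dtplan gamma      --reference ref.nii.gz --evaluated ev.nii.gz --out gamma.json
dtplan logcheck   --log delivery.csv --out logreport.json
```

A config file looks like:

```yaml
case: demo
prescription_gy: 50
normalization: D95->100%
settings:
  gantry_step_deg: 2
  gradient_limit: 3
  smoothing_window: 10
  clearance: {gantry_clearance_radius_mm: 400, safety_margin_mm: 20}
  envelope:  {box_min_mm: [-250, -200, -900], box_max_mm: [250, 120, 900], ct_extent_mm: [-156, 156]}
paths:
  - {name: p1, oars: [parotid_l, parotid_r], strategy: split-field}
  - {name: p2, oars: [cord], strategy: collimator-offset-90}
```

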