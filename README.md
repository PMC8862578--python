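# pediplan

CT-value-driven pedicle screw trajectory planning.

Pedicle screw fixation fails most often where it is needed most: in
osteoporotic vertebrae, where low bone mineral density (BMD) reduces the
pull-out force of the screw. Because CT attenuation in Hounsfield units (HU)
is linearly related to BMD, the mean HU of the bone a screw occupies is a
practical surrogate for its expected purchase. `pediplan` implements an
automatic planner that searches for the screw corridor maximizing that
surrogate,

    maximize   mean HU over the screw cylinder (entry e, direction u, fixed L x D)
    s.t.       the cylinder stays inside bone (no pedicle or cortical breach),
               it passes through the narrowest pedicle cross-section,
               the tip stays clear of the anterior vertebral cortex,

together with everything needed to study such a planner in silico:

* the conventional **manual baseline** (through the midpoint of the minimal
  pedicle section, parallel to the endplate, on the pedicle axis);
* the standard **axial/sagittal trajectory measurements** — distance to
  midline `d`, axial angle `θ`, distance to the lower endplate `d′`,
  sagittal angle `θ′`, with abduction `90° − θ` and craniocaudal
  inclination `θ′ − 90°` — and signed placement errors `(d₁ − d, θ₁ − θ)`;
* a **T′ densitometry score** `T′ = (CT − CT_ref) / SD_ref`, classifying a
  vertebra osteoporotic at `T′ ≤ −2.5`, plus the comparative group
  arithmetic of a planning study (percent differences, group T′ transforms);
* a **synthetic vertebra phantom** with analytic ground truth and a
  decalcification model (uniform linear HU attenuation of bone toward
  water) emulating an EDTA-demineralised in vitro osteoporosis model.

The package is aimed at researchers evaluating trajectory-planning
algorithms and at engineers who need a reproducible, oracle-testable
reference implementation; it is not a clinical device.

## Worked example

```python
import pediplan as pp

# a synthetic vertebra with a dense corridor planted through the left
# pedicle waist, tilted toward the upper endplate
spec = pp.with_corridor(pp.PhantomSpec(seed=3))
ct, labels, truth = pp.generate_phantom(spec)
frame = pp.frame_from_truth(truth, "left")

manual = pp.plan_manual(ct, labels, frame, "left")          # 6 x 30 mm screw
auto = pp.plan_auto(ct, labels, frame, "left",
                    settings=pp.SearchSettings(entry_patch_half_extent=2.0,
                                               cone_half_angle=12.0,
                                               angular_step=2.0))
for name, res in (("manual", manual), ("auto:  ", auto)):
    m = pp.measure_trajectory(res.trajectory, frame)
    print(f"{name} corridor: {res.mean_hu:.1f} Hu, abduction {m.abduction:.1f} deg, "
          f"craniocaudal {m.craniocaudal:.1f} deg")
print(f"auto vs manual:  +{pp.percent_difference(auto.mean_hu, manual.mean_hu):.1f}%")
print(f"corridor axis recovered to "
      f"{auto.trajectory.axis().angle_to(truth.corridor_axis):.2f} deg")

factor = pp.calibrate_decalcification(-3.0, 2767.87, 26.15, ct, labels)
decal = pp.apply_decalcification(ct, labels, factor)
tp = pp.t_prime(pp.vertebral_mean_hu(decal, labels), 2767.87, 26.15)
print(f"decalcification factor {factor:.4f} -> T' = {tp.t_prime:.2f} "
      f"(osteoporotic: {tp.osteoporotic})")
```

prints

```
manual corridor: 3252.0 Hu, abduction 15.1 deg, craniocaudal 0.0 deg
auto corridor:   3335.5 Hu, abduction 15.3 deg, craniocaudal -6.7 deg
auto vs manual:  +2.6%
corridor axis recovered to 0.59 deg
decalcification factor 0.9529 -> T' = -3.00 (osteoporotic: True)
```

The automatic plan tilts off the pedicle axis to follow the planted dense
corridor (recovering its axis to 0.6°), scores higher than the manual
baseline, and remains fully contained in bone. The calibration drives the
phantom's whole-vertebra mean CT value to a target T′ of −3.0 against the
reference population (2767.87 ± 26.15 Hu), past the −2.5 osteoporosis
threshold.

The same workflow is available from the shell:

```bash
pediplan phantom --out ct.nii.gz --labels labels.nii.gz --truth truth.json --seed 2
pediplan plan-auto --ct ct.nii.gz --labels labels.nii.gz --side left \
    --out traj.json --report plan.json
pediplan feasibility --ct ct.nii.gz --labels labels.nii.gz --traj traj.json --side left
pediplan export-guide --traj traj.json --out guide_points.csv
pediplan tprime --ct-mean 2688.80 --ref-mean 2767.87 --ref-sd 26.15
pediplan report --groups groups.csv
```

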