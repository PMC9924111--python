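# fifplan

Automated **field-in-field (FIF)** forward planning for whole-brain
radiotherapy (WBRT), on synthetic head phantoms.

WBRT delivers a palliative prescription — typically 30 Gy in 10 fractions —
through two parallel-opposed lateral 6 MV beams shaped to the brain in the
beam's-eye-view (BEV). Because the head is narrower at the vertex than at
mid-skull, parts of the skull and scalp sit on short ray paths and receive
well over the prescription: *hotspots*. The FIF technique removes them by
adding small subfields inside the main fields whose multi-leaf collimator
(MLC) leaves block the current high-dose region, then rebalancing beam
weights. Doing this by hand is slow and expertise-bound; `fifplan`
implements it as a fully automatic loop, aimed at anyone studying
forward-planning automation (medical physicists, planning-algorithm
researchers) who needs a self-contained, inspectable sandbox rather than a
commercial treatment planning system.

## The algorithm

A *hotspot* is any connected volume larger than 1 cm³ receiving ≥ 107% of
the prescription dose Rx. Plans are normalized so that 99.9% of the brain
volume receives 100% of Rx. Starting from an equal-weight opposed-lateral
plan, each iteration:

1. measures the maximum hotspot percentage `h` on the normalized plan;
2. picks the block level `b = max(h − 3, 107)` (% of Rx) — a fixed 3%
   decrement, e.g. a 116% hotspot is blocked at the 113% iso-dose level;
3. conforms an opposed subfield pair to the main aperture minus the BEV
   projection of the supra-`b` region (the opposed member is the left-right
   mirror, so both block the same anatomy);
4. re-optimizes all beam weights `w` with bounded L-BFGS-B against
   `C(w) = Σ_body max(0, D_v(w) − Rx)² + Σ_brain max(0, Rx − D_v(w))²`,
   with `D(w) = Σᵢ wᵢ Dᵢ` and every field held at ≥ 5 MU, then renormalizes;
5. accepts the iteration only if the hotspot volume did not grow.

The loop stops when the target level is reached (no hotspot above 107%),
when six subfields have been added, or when adding subfields would enlarge
the hotspot (the pair is then withdrawn). All of these settings are
configuration, not constants.

Dose comes from a deliberately simple raycast engine
(`T(u,v) · (SAD/r)² · B(d)`: aperture transmission, inverse square, and a
build-up-ramp/exponential depth-dose in radiological depth), which
reproduces the opposed-lateral hotspot geometry without claiming clinical
dosimetry. Phantoms are parametric: an ellipsoidal soft-tissue head with a
bone shell, brain, eyes and lenses, with presets spanning four regimes
(`default`, `stress`, `mild`, `flat` — from persistent hotspots to none).

## Worked example

```sh
$ fifplan run --out out/demo          # default phantom, default settings
...
FIF finished (max_subfields): V107% 845.5 -> 834.8 cm3, max hotspot 130.7% -> 120.7%
```

`out/demo/metrics.txt` holds the before/after report:

```
           metric  initial_plan  fif_plan
     brain_d99_gy        30.032    30.032
     brain_d95_gy        30.256    30.255
      brain_d1_gy        34.340    34.340
         v107_cm3       845.480   834.832
v107_pct_of_brain        69.035    68.166
  max_hotspot_pct       130.654   120.690
```

Reading: brain coverage (D99 ≈ 30 Gy, i.e. 99% of the brain at or above the
prescription) is untouched while the peak dose falls from 130.7% to 120.7%
of Rx — this default head is deliberately harsh, so the loop spends its full
six-subfield budget and stops. On the `mild` preset the loop converges
instead:

```sh
$ printf 'phantom:\n  preset: mild\n' > mild.yaml
$ fifplan run --config mild.yaml --out out/mild
FIF finished (target_reached): V107% 29.4 -> 0.0 cm3, max hotspot 108.5% -> 107.0%
```

Every run writes the phantom (NIfTI), both plan files (YAML with per-leaf
intervals, weights and MU), both normalized dose grids, a per-iteration log
(`iterations.csv`: pre-iteration max hotspot %, block threshold, hotspot
volume before/after, accepted flag, stop reason), DVH curves per structure,
and a copy of the config — a rerun from that config is byte-identical.

Other subcommands: `fifplan phantom` (generate grids/masks only),
`fifplan init-plan` (normalized opposed pair, no FIF), `fifplan evaluate`
(metrics for an existing dose grid), `fifplan report` (merge two metric
files into a before/after table).

## Layout

```
src/fifplan/
  grids.py     voxel grids + structure masks, NIfTI I/O
  phantom.py   parametric head phantoms and regime presets
  bev.py       beam geometry, BEV projection, MLC conformance, apertures
  dose.py      raycast dose engine (radiological depth, build-up, ISq)
  plans.py     Field/Plan containers and YAML plan files
  optimize.py  L-BFGS-B beam-weight optimization, coverage normalization
  fif.py       hotspot detection and the FIF iteration loop
  evaluate.py  DVHs, Dx/Vx lookups, plan metric reports
  config.py    validated YAML run configuration
  pipeline.py  end-to-end orchestration and artifact writing
  cli.py       `fifplan` command-line interface
  dicomrt.py   minimal DICOM RT Dose export
docs/methods.md   model, assumptions, parameter choices, limitations
```
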