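# echolv

Automated measurement of left-ventricular (LV) linear dimensions from
long-axis echocardiographic frames, and the multi-reader consensus framework
for validating any measurer — human or automated — against a panel of
experts.

## The problem

Three linear dimensions anchor LV assessment on a right-parasternal
4-chamber view: interventricular septal thickness (IVS), LV internal
diameter (LVD) and free-wall thickness (FW). Clinicians measure them by
placing four caliper points along a measurement axis — the anterior and
posterior borders of the septum (`SEPT_ANT`, `SEPT_POST`) and of the free
wall (`FW_ANT`, `FW_POST`) — so that

```
IVS = ‖SEPT_ANT − SEPT_POST‖,  LVD = ‖SEPT_POST − FW_ANT‖,  FW = ‖FW_ANT − FW_POST‖
```

with distances taken in cm via the per-axis pixel spacing. `echolv`
automates the point placement by Gaussian-heatmap keypoint regression: a
U-Net-style network predicts, for each landmark, a confidence map whose
target is `exp(-‖q − p‖²/2σ²)` (σ = 15 px at 320×320), plus a *pseudo-line*
channel — a Gaussian ridge through all four landmarks — that encourages
collinear, correctly ordered predictions. Peaks are decoded to sub-pixel
coordinates (log-quadratic refinement, exact for Gaussian peaks), mapped
back to native pixels, and converted to calipers with geometric sanity
flags.

Because a single expert is not a trustworthy reference, validation uses a
consensus panel: 13 experts measure every frame twice (26 labels), the
per-frame consensus is their mean, and a candidate is judged by whether its
deviations from that consensus disperse like an individual expert's
(Levene/Brown–Forsythe test) and whether it is biased (paired t test).

The package ships a synthetic phantom generator (fan-shaped sector, two
bright wall bands crossed by the measurement axis, Rayleigh speckle) with
exact ground truth and a stochastic 13×2 rater simulator, so the whole
pipeline is exercisable and testable with no data download.

## Worked example

```python
from echolv.evaluation import parameter_recovery, consensus_recovery

r = parameter_recovery(seed=7)        # trains a small net on 200 phantoms
print(f"keypoint error  {r.mean_keypoint_error_px:.2f} px")
print(f"thickness error {100 * r.mean_thickness_error_frac:.1f} %")

result, closed_form = consensus_recovery(seed=7, n_frames=50)
print(result.summary[["phase", "site", "expert_dev_sd"]].head(3))
print(f"closed form {closed_form:.4f} cm")
```

prints (a few minutes, one CPU):

```
keypoint error  2.03 px
thickness error 9.0 %
  phase site  expert_dev_sd
0    ED  IVS       0.053384
1    ED  LVD       0.055813
2    ED   FW       0.056561
closed form 0.0566 cm
```

The first block trains a depth-2, base-8 U-Net at 128 px for 10 epochs on
200 phantoms and scores 50 held-out phantoms: landmarks are recovered to
~2 px and the derived calipers to ~9 % of truth (typical range across seeds:
1.5–2 px, 5–9 %). The second simulates a
13-expert × 2-repeat panel whose per-point thickness noise is σ_t = 2 px at
0.02 cm/px: the pooled expert dispersion matches the closed form
√2·σ_t·spacing ≈ 0.057 cm, and the structurally-zero mean column mirrors the
layout of a published reader-study table.

More narrative scripts live in `examples/` (phantom cohorts, the heatmap
codec, training, consensus validation). A thin CLI wraps the same library
calls:

```sh
echolv phantom --n 200 --out cohort/ --seed 7 --raters
echolv train   --data cohort/ --out model/ --config train.toml
echolv predict --model model/ --frames cohort/annotations.jsonl --out preds.jsonl
echolv measure --points preds.jsonl --out measurements.csv
echolv validate --measurements measurements.csv --candidate AI --out summary.csv
echolv demo --seed 7 --out demo/     # the whole loop at toy scale
```

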