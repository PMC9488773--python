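# sentinelcam

Camera-based sentinel-prey analysis for field ecology.

Sentinel-prey experiments measure predation pressure by deploying live prey
— here, adult banana weevils (*Cosmopolites sordidus*) tethered to a
30 × 30 cm tile — and recording who eats them. A fixed camera photographs
the tile every 30 s for 24 h, producing ~3 000 images per session of which
only a handful show anything. This package implements the image-analysis
and statistics half of such a study:

1. **Change detection.** Every frame `I_i` (reduced to 300 × 400 grey
   pixels) is compared with a rolling-average background `Î`, the pixel-wise
   mean over a 50-frame window centred on `i`. A pixel counts as changed
   when `|p̂ − p_i| > 70` (grey levels of 255); the per-frame changed-pixel
   proportion is screened adaptively, selecting frame `i` for manual review
   when its proportion exceeds `μ_i + 2σ_i`, the rolling mean plus two
   rolling standard deviations of the proportion itself. A static scene
   selects nothing; any sudden intrusion covering ≥ 1 % of the frame at
   sufficient contrast is always selected.
2. **Event analysis.** Reviewed frames (species, feeding flag, number of
   weevils still visible) are clustered into *appearances* (maximal runs of
   consecutive frames showing one species); each unit drop in the
   visible-weevil count is a *predation event*, attributed to the species
   appearing within ±4 frames (2 min) of the disappearance — with a feeding
   observation overriding distance — or to `"unseen"` otherwise. Summary
   statistics follow the field conventions: predation rate
   (events / prey deployed), per-species event shares, and predation
   frequency (appearances involved in predation / total appearances).
3. **Temporal model.** Hourly event counts are fit with a Poisson GLM on
   first-order circular harmonics, `log λ(h) = b₀ + b_s sin(2πh/24) +
   b_c cos(2πh/24)`, giving an activity amplitude, a peak hour, and a
   2-df likelihood-ratio test against constant activity.
4. **Synthetic data.** Because the pipeline is built for imagery that
   cannot ship with code, a generator renders fully-specified synthetic
   sessions — textured tile, illumination drift, flash failures, elliptical
   animal blobs, vanishing weevil marks — with exact ground truth, so every
   stage is testable end to end.

## Worked example

The numbered scripts under `analysis/` run a reduced synthetic study
(2 plots × 2 tiles × 2 sessions, 600 frames each spanning 24 h):

```bash
python analysis/01_simulate_study.py
python analysis/02_detect_visits.py
python analysis/03_extract_events.py
python analysis/04_temporal_model.py
```

which prints, among other things:

```
8 sessions, 2 true predation events ({'S. murinus': 2})
overall review load 1.79% (86 of 4800 frames); all visible events caught: True
2 events recovered (truth 2); per-species match: True
predation rate 12.5% of 16 deployed weevils; sessions zero/one/both = 7/0/1
amplitude 1.545 +/- 0.145 (true 1.5), peak hour 22.36 (true 22), LRT p = 1.67e-36
```

Read: the adaptive detector reduced 4 800 frames to 86 needing human eyes
(1.8 % review load) without missing any event frame; the event pipeline
reconstructed the generator's predation record exactly (both weevils of one
session taken by the simulated shrew, hence one "both" session among
eight); and the harmonic Poisson fit recovered the simulated nocturnal
activity peak (true amplitude 1.5 at hour 22) within one standard error.

The same machinery is exposed as a CLI for real image directories:

```bash
sentinelcam simulate --out study/ --seed 5 --small --render
sentinelcam detect   --input study/frames --out study/detect
# ... manual review produces annotations.csv ...
sentinelcam analyze  --annotations study/annotations.csv \
                     --sessions study/sessions.csv --out-dir study/analysis
sentinelcam report   --analysis-dir study/analysis
```

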