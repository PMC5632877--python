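# bei — Brain Engagement Index from single-channel EEG

`bei` implements a real-time attention/engagement marker for neurorehabilitation:
the **Brain Engagement Index (BEI)**, computed from one frontal EEG channel
(nominally Fpz referenced to the earlobe, 512 Hz) by matching a 1500 ms
averaged-ERP template against the delta-filtered raw signal. It is aimed at
researchers studying patient engagement during therapy — where a live, scalar,
single-electrode marker is practical and a multielectrode lab montage is not —
and at anyone who wants to reanalyze or simulate such monitoring offline.

The package covers the full analysis chain around the marker:

- **engine** — streaming BEI computation with the artifact-rejection cascade,
- **session metrics** — a per-session engagement grade and the therapist
  feedback escalation ladder,
- **statistics** — paired-session nonparametric outcome tests,
- **synthetic data** — seeded EEG and rating generators with ground truth, so
  everything is exercisable without clinical recordings.

## The marker

Every 10 seconds the engine analyzes the preceding 60 s of signal:

1. cut the minute into six 10 s segments; bandpass each to the delta band
   (1–4 Hz, zero-phase Butterworth) and min–max normalize to [−1, +1];
2. slide a 1500 ms window (one-sample stride) across each normalized segment
   and compute its mean absolute distance *d* to the normalized template;
   *d* < 0.5 is a **match**, otherwise a **no-match**, with overlapping events
   of the same kind counted once;
3. the segment BEI is `matches / no-matches`, clamped so BEI ∈ [0, 1];
4. the emitted BEI is the median of the six segment values.

Noise handling: a 1500 ms window whose delta-activity amplitude has an
SD/mean ratio above 1 is rejected; more than one non-overlapping rejected
window discards the segment; fewer than three clean segments leave the minute
without a BEI (an explicit gap, never interpolated).

Session level: all BEI samples of a patient's two monitored sessions are
pooled; each session is graded by the fraction of its samples above the
pooled mean + 1 SD (the *BEI session*). During live monitoring the feedback
ladder advises the therapist whenever the BEI drops more than 10% below the
patient's running average for at least 30 s: first encourage, then change the
exercise difficulty, then suggest rest or passive exercise.

The study's own ERP template is proprietary; the package ships a clearly
labelled synthetic surrogate (a 1500 ms mid-delta burst) and every function is
template-agnostic — pass `--template your_waveform.csv` to use a real one.

## Worked example

```python
import numpy as np
from bei import (SynthSpec, SessionPair, default_template, gen_recording,
                 session_bei, stream_bei)

fs = 512.0
tpl = default_template(fs)

# 3-minute synthetic session: engaged (3 template occurrences / 10 s)
spec = SynthSpec(duration_s=180, fs=fs, embed_rate=3.0, artifact_rate=1.0, seed=42)
rec, truth = gen_recording(spec, tpl)          # truth: 54 embedded onsets
trace = stream_bei(rec, tpl)

for t, v in zip(trace.times_s[:3], trace.values[:3]):
    print(f"t={t:5.0f} s  BEI={v:.3f}")
print("mean BEI: %.3f" % np.nanmean(trace.values))
```

```
t=   60 s  BEI=0.667
t=   70 s  BEI=0.667
t=   80 s  BEI=0.667
mean BEI: 0.686
```

The first value appears at t = 60 s (one full analysis window) and one value
follows every 10 s. Comparing against a second, less engaged session
(`embed_rate=0.5`, seed 43):

```python
spec2 = SynthSpec(duration_s=180, fs=fs, embed_rate=0.5, artifact_rate=1.0, seed=43)
trace2 = stream_bei(gen_recording(spec2, tpl)[0], tpl)
res = session_bei(SessionPair(trace, trace2))
print(f"threshold={res.threshold:.3f}  fractions: {res.fraction_above_fb:.3f} "
      f"vs {res.fraction_above_nofb:.3f}  higher={res.higher_session}")
```

```
threshold=0.707  fractions: 0.154 vs 0.000  higher=feedback
```

The pooled mean + 1 SD threshold is 0.707; 15.4% of the engaged session's
BEI samples exceed it against 0% of the disengaged session's, so the engaged
session is correctly graded higher.

## Command line

```sh
bei compute --input rec.edf --template tpl.csv --out trace.csv
bei session --trace-a fb.csv --trace-b nofb.csv --out session.json
bei advise  --trace fb.csv --out events.csv
bei stats   --scores scores.csv --pairing pairing.csv --out stats.json
bei synth   --seed 7 --out rec.csv --truth truth.csv
```

Every output gets a `.manifest.json` sidecar (version, config hash, input
digests, seed) for exact reruns. Defaults equal the study constants.

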