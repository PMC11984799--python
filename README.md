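# dmc-behavior

A hardware-free re-implementation of the computational core of a
steering-wheel, head-fixed auditory decision-making platform: tone-cloud
stimulus synthesis, quadrature wheel decoding, event-driven trial state
machines for detection / Go-NoGo / 2AFC tasks with fully automated staged
training, simulated mouse agents with parameterized psychometric ground
truth, signal-detection and psychometric analyses, and device
synchronization utilities. Everything runs closed-loop on a virtual clock —
no rig required.

## Modules

| module        | what it does |
|---------------|--------------|
| `stimuli`     | 12-TET pitch table (C7–B9), tone-cloud sampling/synthesis (100 tones/s, 30 ms tones, 3 ms raised-cosine ramps, 44.1 kHz), white noise, WAV I/O |
| `wheel`       | quadrature decoding (1,024 PPR, ×1 counting) to 100 Hz cumulative angle, velocity, quiescence and turning-goal detection, accumulated turning |
| `task_engine` | trial/session FSMs for pretraining, detection, Go/NoGo and 2AFC: quiescence → stimulus (repeated until response or window end) → outcome → reward / timeout / noise → ITI; pseudorandom trial ordering with repeat limits and debiasing; disengagement rules; 10 ms tick clock so logged interval durations are exact |
| `agents`      | simulated mice: erf psychometric ground truth (lapses, bias, slope), log-normal RTs, impulsive pre-stimulus turning, disengagement; named profiles (`ideal`, `lapsing`, `biased`, `impulsive`, `disengaging`, `never_responding`) |
| `training`    | multi-session automation: stage advancement thresholds, intersession reward-size adjustment (±0.1 µl, clamped), >85 % turn-bias reward doubling, d′ / psychometric proficiency criteria |
| `analysis`    | H/F rates, d′ with 1/(2N) clamping, MLE psychometric fits, rolling window-10 performance, RTs, pre-stimulus-turning→RT regression, turn bias, first-20-min filter |
| `sync_io`     | 30 Hz pulse schedules, dropped-frame detection, nearest-pulse event alignment, HDF5 session store (+ CSV trial table mirror) |

## CLI

```bash
dmcb run --task 2afc --stage 4 --agent lapsing --seed 7 --out sessions/
dmcb simulate-training --task gonogo --agent ideal --sessions 10 --seed 1 --out progress.csv
dmcb fit-psychometric sessions/session_2afc_stage4_seed7.h5
dmcb report sessions/session_2afc_stage4_seed7.h5
dmcb gen-stimuli --strength 70 --octave high --seed 3 --out cloud.wav
dmcb align pulses.txt --rate 30 --events events.txt
```

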