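# falldet

Falls are the leading cause of injury among older adults, and a wrist-worn
detector — a smartwatch — is the form factor people actually keep on. But a
watch is a hostile compute target: little RAM, no threads, and a battery
budget that punishes every extra sensor read. `falldet` implements, as a
tested Python library, the full design loop for such a detector:

* an **offline study pipeline** — sliding-window labeling of triaxial
  recordings, the low-cost FS-1 feature set, and an exhaustive
  (frequency × window size × algorithm × feature subset) configuration grid
  scored by 5-fold cross-validation;
* an **online simulator** of the deployed detector — sequential
  collect/classify cycles with a classification dead zone, streaming
  feature updates, a memory-capped dataset, and a user-feedback learning
  loop that turns false alarms into training points;
* a **synthetic data generator** that emulates the acquisition campaign
  (14 young participants × 19 activities × 3 repetitions, 4 for the F08
  fall; an elder cohort with reduced-intensity ADLs), so the whole pipeline
  is testable without the original recordings.

It is aimed at researchers in wearable human-activity recognition who want
a reproducible, end-to-end reference implementation of this detector
family.

## The model

A recording is windowed into half-open slices $[t, t+w)$ taken every
`jump` seconds. A window from a fall file is labeled **Fall** when it
covers at least 50 % of the manually delimited *actual fall* interval
(mean duration ≈ 3.10 s); ADL (activity of daily living) files only yield
**ADL** windows. Each window is summarised by the FS-1 features —
maximum, minimum, mean and sample variance per axis — computed either in
batch or recursively per reading $x$ with counter $N$:

$$m_N = m_{N-1} + \frac{x - m_{N-1}}{N}, \qquad
  s^2_N = \frac{(N-2)\,s^2_{N-1} + (x - m_{N-1})(x - m_N)}{N-1},$$

so the watch never buffers raw samples. Classification is k-nearest
neighbours with Euclidean distance
$d(a,b) = \sqrt{\sum_i (a_i - b_i)^2}$; the deployed configuration is
**accelerometer-only FS-1, 3NN, 9 s windows at 50 Hz** (450 samples per
window). Detection quality is reported as accuracy, sensitivity
$TP/(TP+FN)$ and specificity $TN/(TN+FP)$ with Fall as the positive class.

The default study grid spans 5 rates × 5 window sizes × 15 algorithms
(10 kNN, 2 SVM, 3 decision-tree variants) × $2^{12}-1 = 4095$ feature
subsets = 1 535 625 configurations; SVM and trees delegate to
scikit-learn, kNN and everything on the simulated watch is implemented
from scratch.

## Worked example

```sh
$ python examples/03_cross_validation.py
  50 Hz: accuracy 0.99517 (sd 0.00279), sensitivity 0.98879, specificity 0.99897  [3103 windows]
   5 Hz: accuracy 0.99065 (sd 0.00385), sensitivity 0.98447, specificity 0.99434  [3103 windows]
```

This generates the full synthetic young-participant campaign (812
recordings), extracts 3103 labeled 9-second windows, and cross-validates
the deployed configuration. At 50 Hz the detector catches 98.9 % of fall
windows while disturbing 0.1 % of ADL windows; dropping the sampling rate
to 5 Hz blurs the short impact spikes and costs about half a point of
accuracy — the direction that justifies spending battery on the full rate.

```sh
$ python examples/05_online_simulation.py
seed dataset: 234 points ({'ADL': 142, 'Fall': 92})
session: 63 classifications over 613 s, dead time 45.7 s
false alarms: 4 in the first half, 1 in the second
battery: detector draws 0.03 W vs 0.007 W baseline -> extra 0.023 W, 0.552 Wh per day
```

Here a wearer the detector has never seen claps repeatedly: early claps
trigger false alarms, the denied detections are stored as ADL points, and
the same movement stops triggering later in the session. The other
examples cover dataset generation and bookkeeping (`01`), windowing and
streaming-vs-batch features (`02`), and grid search (`04`).

A thin CLI mirrors the examples: `falldet generate | inspect | windows |
grid | simulate` (see `falldet --help`).

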