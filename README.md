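# emotrack

Consensus-based scoring and item analysis for **continuous emotion
tracking** experiments.

In inferential emotion tracking (IET) paradigms, observers watch short
movie clips and continuously rate the affect of a target character —
whose face is blurred out — on a 2-D valence–arousal grid, so that only
spatial and temporal *context* carries the emotional information. There
is no objective ground truth for such ratings; instead, the "correct"
trajectory is estimated from the raters themselves with an **informal
cultural consensus model**: for each video and dimension, all raters'
standardized time series enter a principal component analysis, and the
first component's factor scores — a weighted linear combination that
up-weights mutually consistent raters — serve as the consensus
trajectory. A rater's accuracy on a video is the Pearson correlation *r*
between their own series and the consensus, and accuracies are pooled by
Fisher-Z averaging:

    accuracy = tanh( mean( atanh(r_1), …, atanh(r_k) ) )

Around this core, the package provides the full analysis battery such a
study needs:

* **reliability diagnostics** — percentile-bootstrap CIs for
  per-participant and per-video accuracy; a permuted accuracy null built
  from random circular time shifts; the video *difficulty function*
  (videos ranked by pooled accuracy) and a leave-one-out procedure that
  flags random responders whose own difficulty function is consistent
  with a video-label permutation null;
* **trait associations** — Table-style descriptives (mean, median, SD,
  range, skewness, excess kurtosis), Spearman correlations between
  accuracy and questionnaire totals (AQ, EQ, Eyes Test, Films task,
  fluid/crystallized intelligence, …) with Bonferroni correction over a
  declared 17-comparison plan, partial Spearman correlations
  (rank-then-residualize) with case-resampling bootstrap CIs, and
  permutation tests;
* **video item analysis** — Monte-Carlo subset curves (effect size as a
  function of the number of videos), the minimum number of videos
  reaching 75% of the full effect, best-video selection, five-chunk
  split-sample reliability, and median/quartile trait splits with
  bootstrap group tests;
* a **synthetic cohort generator** with known ground truth (latent
  Ornstein–Uhlenbeck affect trajectories, per-rater competency, gain,
  bias, lapses, and Gaussian-copula questionnaire totals whose AQ loads
  on competency), so every stage is testable end to end without human
  data.

## Worked example

```python
import pandas as pd
import emotrack as et
from emotrack.association import correlation_battery, bootstrap_partial

# reference conditions: 102 raters x 35 clips of 1-3 min at 10 Hz,
# competency loading on AQ at -0.4
ratings, quests, truth = et.generate_cohort(et.SyntheticConfig(seed=11))
acc = et.score_study(ratings)

pv = acc.pooled_series("valence").rename("iet_valence")
pa = acc.pooled_series("arousal").rename("iet_arousal")
scores = pd.concat([pv, pa], axis=1).reset_index()
head = next(r for r in correlation_battery(scores, quests)
            if r.x == "iet_valence" and r.y == "aq" and not r.label)
print(f"valence accuracy: mean={pv.mean():.3f}  range=({pv.min():.3f}, {pv.max():.3f})")
print(f"valence ~ AQ: rho={head.rho:.3f}  p={head.p_uncorrected:.2g} "
      f"(Bonferroni x17: {head.p_bonferroni:.2g})")
```

prints

```
valence accuracy: mean=0.731  range=(0.315, 0.953)
valence ~ AQ: rho=-0.465  p=8.5e-07 (Bonferroni x17: 1.4e-05)
```

— pooled tracking accuracy sits around 0.7 with wide individual spread,
and the rank correlation between valence-tracking accuracy and AQ comes
out negative (higher autism-quotient scores go with worse context-based
tracking) and survives correction for the 17 planned comparisons.
Controlling for fluid and crystallized intelligence leaves it intact:

```python
joined = scores.merge(quests, on="participant_id")
part = bootstrap_partial(joined["iet_valence"], joined["aq"],
                         [joined["matrices"], joined["vocabulary"]],
                         B=2000, seed=0, covariate_names=["matrices", "vocabulary"])
print(f"partial: mean rho={part.rho:.3f}  95% CI [{part.ci95[0]:.3f}, {part.ci95[1]:.3f}]")
# partial: mean rho=-0.436  95% CI [-0.584, -0.266]
```

The same pipeline is available from the shell:

```bash
emotrack simulate --out cohort --seed 11
emotrack run --ratings cohort/ratings.csv \
             --questionnaires cohort/questionnaires.csv \
             --out results --seed 11
```

which writes per-stage CSV/JSON artifacts plus `report.json` /
`report.txt`; re-running with the same inputs and seeds reproduces every
byte.

## Layout

| module | contents |
| --- | --- |
| `emotrack.synthetic` | `SyntheticConfig`, latent-trajectory and cohort generators, cohort CSV writer |
| `emotrack.consensus` | rating-matrix assembly, first-factor consensus, accuracy scoring, Fisher-Z pooling |
| `emotrack.reliability` | bootstrap CIs, circular-shift accuracy null, difficulty functions, responder flags |
| `emotrack.association` | descriptives, Spearman / partial Spearman, Bonferroni, bootstrap and permutation inference, the comparison battery |
| `emotrack.video_selection` | subset curves, best-video selection, split-sample reliability, group splits |
| `emotrack.io` / `emotrack.pipeline` / `emotrack.cli` | CSV contracts, end-to-end orchestration, command line |

See `docs/methods.md` for the statistical model, parameter defaults and
known limitations.
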