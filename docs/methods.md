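# Methods

`driftstate` classifies the GPS fixes of satellite-tracked buoys attached to
drifting fish-aggregating devices (dFADs) into two behavioural states —
"at sea" (S, drifting on the ocean) and "on board" (B, carried by a purse
seiner) — and derives drift statistics, fishing-set locations, beaching
events and ineffective-effort measures from the classified tracks. Because
real fleet tracking data are confidential, the package ships a synthetic
fleet simulator with known ground truth; every stage of the pipeline is
validated against that truth.

## The classification problem

A buoy track is a succession of onboard and at-sea phases. Onboard fixes
move at vessel cruising speed (2–7 m/s) except during fishing sets and port
calls, when the vessel is nearly stationary; at-sea fixes drift at well
under 1 m/s. A plain speed filter therefore separates most fixes but
mislabels the slow onboard fixes — that overlap is the reason multivariate
classifiers are compared. Four methods are implemented behind one surface:

- **VEL** — speed filter. The threshold is the maximum speed observed among
  at-sea fixes in the training data; classification is `speed <= threshold
  -> S` (inclusive, because the threshold is defined as an observed
  maximum).
- **MLR** — L2-penalised logistic regression (weight decay `w` maps to the
  inverse regularisation strength; `w = 0` is effectively unpenalised).
- **ANN** — single-hidden-layer perceptron with `s` hidden units and weight
  decay `w`.
- **RF** — random forest with `mtry` candidate variables per split.

Each position carries 12 predictors computed from the triplet of fixes
(t−1, t, t+1): time intervals after/before/spanning, speed and speed
before (m/s), acceleration `2*(speed − speed_before)/dt_after` (the factor
2 is retained as printed in the defining formula; it is a monotone rescale
that classifiers are indifferent to), heading change, minimum great-circle
distance to a port (km), and water temperature with its lag, difference and
rate. Heading change defaults to the *literal* difference of absolute
bearings, which conflates turns across north; the conventional
smallest-signed-turn variant is available via `heading_mode="turn"`.
Boundary fixes copy their one-sided values into the missing side so that
every position is classifiable — no row is dropped.

MLR and ANN are standardized in-pipeline; RF is not (tree splits are
scale-free). Tuning follows the bootstrap protocol: for each grid point,
`n_boot` resamples of the training rows are fitted and scored on the
out-of-bag rows by accuracy and Cohen's Kappa; the grid point with the best
mean accuracy wins, Kappa breaking ties lexicographically (the joint
"accuracy and Kappa" objective is not otherwise defined). During bootstrap
scoring the forest is shrunk to `rf_boot_trees` (default 60) trees to keep
desk runs fast; the winning configuration is refitted with the full
`rf_trees` (default 200). Probabilities are cut at 0.5; an optional
sensitivity+specificity-maximising threshold and a majority-subsampling
rebalance flag exist but are off by default, since neither improves
performance.

Cross-validation splits by *trajectory*, never by position: the buoy ids
are randomly halved `n_repeats` times (default 20, unstratified), each
method is calibrated on one half and scored on the other with five
indicators — error rate, precision, True Sea Rate, False Sea Rate, and the
segmentation rate `(segments_pred − segments_obs)/segments_obs` with
segments summed per track. Methods are compared to VEL with paired
two-sided t-tests (α = 0.05) and t-based 95% CIs of the per-repeat
differences.

## Post-processing

Position-wise classifiers produce unrealistic sequences like B S B — a buoy
is not deployed for a few hours. Maximal S runs of length ≤ `max_len`
(default 2, tested range 1–5) flanked by B on both sides are reclassified
to B in a single pass over the original run structure (no cascading; a
`BSBSB` with `max_len=1` becomes `BBBBB` because both runs qualify on the
original sequence). Runs touching a track boundary are exempt: a track may
genuinely begin or end adrift. B runs are never altered.

## Labeling: building the learning set

True states come from superimposing buoy tracks on vessel VMS tracks. The
practice of doing this visually is codified as ordered deterministic rules
parameterised by the stated thresholds: (i) fixes < 5 km from a port are B;
(ii) fixes whose linearly interpolated separation from a candidate vessel
(one with any raw fix < 5 km and < 24 h away) is < 5 km are B, the rest S;
(iii) maximal runs with no VMS support whose speeds are "consistently"
above 1.5 m/s — operationalised as ≥ 90% of the run's finite speeds, since
no quantifier is stated — are left unassigned and excluded from training;
(iv) at B→S transitions the deployment tie-break applies: if speed rises
from t to t+1 the slow fix stays with the vessel. Port-rule and VMS-overlap
conflicts are immaterial (both imply B); the port rule fires first.

## Pre-processing

Three steps in narrative order: drop rows without a valid latitude or
longitude; collapse same-hour fixes of a buoy to their *geographic
midpoint*, computed as the normalised 3-D Cartesian mean on the sphere
(antimeridian-safe, unlike an arithmetic mean) with SST averaged; and
remove "doubled" fixes — identical consecutive coordinates at different
times, a known GPS-capture failure that creates absurd implied speeds —
keeping only the first of each identical run. The chain is idempotent.
Beaching detection runs on the stream *before* doubled-fix removal (the
repeats are its signal), so the chain can tag repeats instead of dropping
them (`keep_repeats=True`).

## Downstream analyses

Maximal S runs become drift trajectories with duration, piecewise
great-circle distance (haversine on the IUGG mean sphere, R = 6371.0088 km)
and an end event (retrieval if followed by B, else track end). S→B
transition points are candidate fishing sets; observed and predicted set
maps are gridded on half-open 1° cells keyed by their floor corner and
compared by Spearman correlation over the union of occupied cells (cells
absent from one map count 0; fewer than 3 occupied cells is flagged
unreliable). Smoothing uses a 2-D product Gaussian kernel with per-axis
normal-reference bandwidths (R's `bandwidth.nrd` rule, a quarter of which
is the Gaussian sigma, matching `MASS::kde2d`, which serves as an
independent oracle in the tests).

Beaching events are maximal runs of ≥ 3 identical raw positions (2 repeats
are a known artifact), excluding runs within 10 km of a port (anchorages)
and flagging runs more than 5 km from the coastline (offshore "stopping
points", reported with and without this final filter). Position equality is
exact by default; a degree tolerance exists for noisy inputs. Coast
distance is the great-circle distance to the nearest coastline segment.
"Recapture month" is the month of a trajectory's final timestamp.

Ineffective effort attributes each inter-fix interval of a trajectory to
the 1° cell of its *starting* fix (a simple, order-preserving convention);
the fraction of drift time outside historical fishing grounds (cells with
at least one recorded set, single-fleet or all-fleet variants) is reported
per trajectory together with per-cell densities of outside positions.

## The synthetic fleet

The generator co-simulates vessels and buoys on an hourly clock inside a
25°×25° tropical basin with a wiggly meridional coastline near its western
edge, ports on the coastline, and a contiguous block of 1° fishing-ground
cells in the centre (≥ 2 cells of margin on every side so "outside the
grounds" is non-empty). Vessels leave port, deploy buoys at the end of
fishing sets, wander between waypoints, and later sail back to a ripe
buoy's drifted position to retrieve it (a pursuit step, so tracks contain
no teleports); retrieval is followed by a set at the FAD. The logbook
records a retrieval set at the FAD's last reported drift position.

At-sea motion is a correlated random walk on the sphere: per-phase mean
heading, AR(1) heading deviation with coefficient `drift_persistence`
(default 0.85, turn noise 18°), speed uniform on (0, 0.8] m/s — strictly
below the 2–7 m/s cruising range, so the speed classes overlap only through
fishing-set and port periods. Emission is irregular: drift fixes at 1/6/12/24 h
(probabilities 0.2/0.3/0.25/0.25 — the real mixture is not published, this
is a configuration choice), hourly in the 12 h before a retrieval and
during sets (fishers densify sampling around visits), 6–12 h at port.
A drift phase lasts 5–16 days (uniform) and a buoy runs 1–3 phases; with
probability `p_beach` (default 0.10) a phase heads for a coastline point
more than 10 km from every port and ends stranded, emitted as ≥ 3 repeats
of the identical recorded coordinates; with probability `p_offshore_stop`
(default 0.05) a phase contains a 24–42 h stationary hold far from the
coast (the offshore "stopping point" the coast filter must remove). SST is
a linear latitudinal gradient plus N(0, 0.2 °C) noise, sensed also while
onboard — it stays a weak predictor by design. Artifact injection adds
same-hour duplicate fixes (2%), doubled fixes (1%) and invalid rows (0.5%),
all flagged so cleaning can be audited.

Default scenario sizes — 5 vessels, 50 buoys, a 45-day horizon — were
chosen once as a desk-scale image of a fishing season: they yield ≈ 3,500
labelled positions on ≈ 50 trajectories with ≈ 12–16% onboard share
(matching the strong at-sea imbalance of real learning sets), drift phases
of 2–3 weeks, and a ~10% beaching fraction. Statistics that need more
trajectories (parameter-recovery checks) scale the buoy count up, not the
physics. What the simulator does *not* emulate: real current fields and
eddies, multi-fleet buoy theft and transfer games, EEZ/piracy geography,
seasonal cycles longer than the horizon, and GPS measurement noise (fixes
are exact, so position repeats are exactly equal — consistent with the
beaching detector's definition). Passing tests therefore demonstrate the
correctness and internal consistency of the pipeline under a realistic
generative model, not oceanographic fidelity.

## Numerical choices and degenerate inputs

Bearings are undefined for coincident fixes; the previous leg's bearing is
carried forward (no turn) so heading features stay finite. FSR is NaN when
no B is observed, precision NaN when no S is predicted; single-trajectory
groups report NaN SD/SE. KDE bandwidth falls back to a small floor on
zero-variance axes. The VEL tie (speed exactly at threshold) classifies S.
All randomness flows from integer seeds through `numpy` `SeedSequence`
spawning; identical seeds give byte-identical outputs, including the CV
splits and bootstrap resamples.

## Known limitations

- The qualitative method ranking (RF best, VEL worst) is reproduced on the
  default scenario, but the margins between RF, MLR and ANN are small —
  the synthetic confusion structure (slow set fixes, port calls) is simpler
  than reality, so all multivariate methods sit closer together than in
  real fleet data.
- Segmentation-driven bias: misclassification splits long drift phases, so
  pipeline-derived mean durations are a few percent short of truth even
  after post-processing; state-sequence models (HMM/HSMM) are out of scope.
- The labeling rules mislabel a handful of fixes at phase boundaries
  (vessel still within 5 km just after deployment); fidelity is ≈ 99%, not
  100%, and those errors concentrate exactly where classification is
  hardest.
- The "at port" buoy analysis is covered only by the port-proximity flag.
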