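# eegmst

Resting-state EEG functional network analysis: band-specific connectivity
(wPLI and leakage-corrected amplitude envelope correlation), minimum
spanning tree topology metrics, and FDR-corrected group comparison — with a
synthetic cohort generator so the whole chain can be validated end to end
without any patient data.

## Who this is for

Researchers comparing scalp-EEG functional network organization between two
groups (e.g. a patient cohort vs matched controls) who want a transparent,
scriptable implementation of the now-standard connectivity + MST workflow,
and a way to check each stage against signals with known ground truth.

## The method

For each subject, the continuous recording is re-referenced to the common
average, band-pass filtered (zero-phase forward–backward Butterworth) into
six bands — delta (0.5–4 Hz), theta (4–7), alpha (7–13), beta (13–30),
lower gamma (30–48), higher gamma (52–70) — and cut into seven 8-s epochs
(4096 samples at 512 Hz). Per epoch, channel-pair coupling is estimated with:

- **wPLI** (delta, theta): with analytic signals $z_i, z_j$,

  $\mathrm{wPLI} = \dfrac{|\langle \mathrm{Im}(z_i z_j^*)\rangle|}{\langle |\mathrm{Im}(z_i z_j^*)|\rangle} \in [0,1]$

  The imaginary cross-spectrum weighting makes zero-lag (volume-conducted)
  coupling invisible; a numerically zero denominator returns 0.

- **AEC-c** (alpha and above): each signal of a pair is regressed on the
  other (pairwise symmetric orthogonalization, removing zero-lag leakage),
  the analytic-signal envelopes are Pearson-correlated in both directions,
  and the two directions are averaged. Values are kept signed.

Connectivity matrices are averaged over epochs; global connectivity is the
mean upper-triangle entry. Per epoch, the spanning tree maximizing total
connectivity (MST on distance $1-w$) is extracted and summarized by
normalized diameter, leaf fraction, maximum degree (raw and /(N−1)),
maximum and regional mean betweenness centrality, and degree assortativity;
metrics are averaged over epochs. Group differences use Welch t-tests with
Cohen's d, Benjamini–Hochberg FDR applied jointly to the 6 global measures
× 6 bands family (36 tests); regional betweenness comparisons are
exploratory and uncorrected.

The synthetic generator produces 55-channel, 512 Hz cohorts whose coupling
follows a prescribed tree (star / path / hierarchical): coupled pairs share
a lagged narrowband carrier and correlated slow log-normal envelopes,
montage-adjacent channels are mixed at zero lag to mimic volume conduction,
and 1/f noise sets the floor — exactly the structure the two estimators are
designed to separate.

## Worked example

`examples/02_connectivity_estimators.py` builds three textbook signal pairs
and prints both estimators:

```
constant pi/3 lag:       wPLI = 1.000   AEC-c = 1.000
zero-lag mixture:        wPLI = 0.070   AEC-c = 0.045
shared envelope:         wPLI = 0.008   AEC-c = 0.944
```

A consistent phase lag saturates wPLI; an instantaneous mixture of one
source (the volume-conduction confound) leaves both estimators at noise
level; a shared slow envelope on independent carriers is invisible to wPLI
but drives AEC-c toward the true envelope correlation.

`examples/04_group_comparison.py` runs the full pipeline on a simulated
6-vs-6 star- vs path-coupled alpha cohort:

```
        measure  band       t     df   direction      p  p_adj       d
   connectivity alpha 25.8585 6.3043 star > path 0.0000 0.0000 14.9294
         max_bc alpha  4.1795 9.9771 star > path 0.0019 0.0028  2.4130
max_degree_norm alpha  4.2626 9.7835 star > path 0.0017 0.0028  2.4610
       diameter alpha -4.6460 7.8695 star < path 0.0017 0.0028 -2.6824
  leaf_fraction alpha  4.3511 8.0446 star > path 0.0024 0.0029  2.5121
  assortativity alpha  2.7138 9.4394 star > path 0.0229 0.0229  1.5668
```

The star-coupled group is recovered as more integrated (higher leaf
fraction, max degree and betweenness; lower diameter), the signature the
MST metrics are meant to detect.

There is also a thin CLI (`eegmst simulate|analyze|stats|run-all`) over the
same library; recordings travel as tab-separated text (header line of
channel labels, `fs=<Hz>` line, one time point per row).

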