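"""Synthetic resting-state EEG cohorts with known coupling structure.

The generator produces clean multichannel recordings whose cross-channel
coupling follows a prescribed tree topology, giving every downstream
estimator a known target:

* **lagged phase coupling** — coupled pairs share a narrowband carrier, the
  receiver's analytic carrier rotated by a fixed phase lag in (0, π), which
  wPLI detects;
* **amplitude-envelope correlation** — each channel's narrowband component
  is multiplied by a slow log-normal modulator; modulators of coupled pairs
  are correlated at a calibrated target, which AEC-c detects;
* **volume-conduction-like leakage** — an instantaneous mixing between
  montage-adjacent channels creates zero-lag correlations that both
  estimators must ignore;
* **1/f background noise** at a configurable signal-to-noise ratio.

Carriers are envelope-normalized narrowband noise (flatten → refilter →
flatten), so the channel envelope equals the slow modulator and the
envelope-correlation target is met analytically; the carriers keep ≥ 95%
of their power inside the target band.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import signal

from .montage import CHANNELS_55, BandSpec
from .preprocess import Recording

#: log-normal modulator scale; the Gaussian-to-log-normal correlation map is
#: inverted with this value, so it only shapes envelope heavy-tailedness.
_MODULATOR_SIGMA = 0.5

#: low-pass cutoff (Hz) of the slow amplitude modulator.
_MODULATOR_CUTOFF_HZ = 0.7

#: carrier std in output units (µV) before noise is added.
_OUTPUT_SCALE_UV = 10.0


def _validate_tree(topology: frozenset[tuple[int, int]], n_channels: int) -> None:
    g = nx.Graph()
    g.add_nodes_from(range(n_channels))
    for a, b in topology:
        if not (0 <= a < n_channels and 0 <= b < n_channels) or a == b:
            raise ValueError(f"invalid topology edge ({a}, {b}) for {n_channels} channels")
        g.add_edge(a, b)
    if g.number_of_edges() != n_channels - 1 or not nx.is_tree(g):
        raise ValueError(
            f"topology must be a connected acyclic tree with {n_channels - 1} edges "
            f"over all {n_channels} channels"
        )


@dataclass(frozen=True)
class CouplingSpec:
    """Coupling structure of one simulated group.

    ``topology`` is a set of undirected channel-index pairs forming a
    spanning tree of the montage. ``phase_lag`` (radians, strictly inside
    (0, π)) is the lag imposed along each edge; ``phase_coupling_strength``
    (0–1) the carrier sharing; ``envelope_correlation`` (0–1) the target
    correlation of coupled pairs' slow modulators; ``leakage_mix`` (0–0.5)
    the zero-lag mixing coefficient between montage-adjacent channels; and
    ``snr`` the coupled-source-to-1/f-background variance ratio.
    """

    topology: frozenset[tuple[int, int]]
    band: BandSpec
    phase_lag: float = math.pi / 4
    phase_coupling_strength: float = 0.7
    envelope_correlation: float = 0.5
    leakage_mix: float = 0.2
    snr: float = 2.0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "topology", frozenset(tuple(sorted(e)) for e in self.topology)
        )
        if not (0.0 < self.phase_lag < math.pi):
            raise ValueError(f"phase_lag must lie strictly in (0, π), got {self.phase_lag}")
        for name, lo, hi in (
            ("phase_coupling_strength", 0.0, 1.0),
            ("envelope_correlation", 0.0, 1.0),
            ("leakage_mix", 0.0, 0.5),
        ):
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ValueError(f"{name} must lie in [{lo}, {hi}], got {v}")
        if not self.snr > 0:
            raise ValueError(f"snr must be positive, got {self.snr}")

    def n_channels(self) -> int:
        return 1 + max(max(e) for e in self.topology)


@dataclass(frozen=True)
class CohortSpec:
    """Study-design parameters shared by all simulated groups."""

    n_subjects: int
    groups: tuple[tuple[str, CouplingSpec], ...]
    fs: float = 512.0
    epoch_length_s: float = 8.0
    n_epochs: int = 7
    montage: tuple[str, ...] = CHANNELS_55
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "groups", tuple(self.groups))
        object.__setattr__(self, "montage", tuple(self.montage))
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        n_samp = self.fs * self.epoch_length_s
        if abs(n_samp - round(n_samp)) > 1e-9:
            raise ValueError(
                f"fs x epoch_length_s = {n_samp} must be an integer sample count"
            )
        if len(set(self.montage)) != len(self.montage):
            raise ValueError("montage labels must be unique")
        for label, spec in self.groups:
            _validate_tree(spec.topology, len(self.montage))
            spec.band.validate_against_fs(self.fs)

    @property
    def samples_per_epoch(self) -> int:
        return int(round(self.fs * self.epoch_length_s))

    @property
    def total_samples(self) -> int:
        return self.samples_per_epoch * self.n_epochs


def make_tree_topology(kind: str, n_channels: int, seed: int) -> frozenset[tuple[int, int]]:
    """A spanning-tree edge set over ``n_channels`` nodes.

    ``star``: one hub linked to all others (maximal integration).
    ``path``: a chain (maximal segregation).
    ``hierarchical``: a balanced binary tree (hub degree ≤ 3).

    The seed permutes which channel plays which structural role, so e.g. the
    hub is not always channel 0.
    """
    if n_channels < 2:
        raise ValueError(f"need at least 2 channels, got {n_channels}")
    if kind == "star":
        edges = [(0, i) for i in range(1, n_channels)]
    elif kind == "path":
        edges = [(i, i + 1) for i in range(n_channels - 1)]
    elif kind == "hierarchical":
        edges = [
            (i, c)
            for i in range(n_channels)
            for c in (2 * i + 1, 2 * i + 2)
            if c < n_channels
        ]
    else:
        raise ValueError(f"kind must be star/path/hierarchical, got {kind!r}")
    perm = np.random.default_rng(seed).permutation(n_channels)
    return frozenset(tuple(sorted((int(perm[a]), int(perm[b])))) for a, b in edges)


def _narrowband_unit_envelope(
    white: np.ndarray, band: BandSpec, fs: float
) -> np.ndarray:
    """Constant-envelope analytic carriers with ≥ ~95% power inside ``band``.

    ``white`` is (channels, samples) white noise; rows are processed jointly.
    """
    sos = signal.butter(4, [band.low, band.high], btype="bandpass", fs=fs, output="sos")
    z = signal.hilbert(signal.sosfiltfilt(sos, white, axis=-1), axis=-1)
    for _ in range(2):
        z = z / np.abs(z)
        z = signal.hilbert(signal.sosfiltfilt(sos, z.real, axis=-1), axis=-1)
    return z / np.abs(z)


def _slow_gaussian(white: np.ndarray, fs: float) -> np.ndarray:
    """Unit-variance low-pass Gaussian processes (the modulators' logs).

    Shaped in the frequency domain with a squared 2nd-order Butterworth
    magnitude response (zero-phase, circular), which avoids the multi-second
    edge transients a time-domain filter would leave at such a low cutoff.
    """
    n = white.shape[-1]
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    gain = 1.0 / (1.0 + (f / _MODULATOR_CUTOFF_HZ) ** 4)
    g = np.fft.irfft(spec * gain, n=n, axis=-1)
    g -= g.mean(axis=-1, keepdims=True)
    sd = g.std(axis=-1, keepdims=True)
    return g / np.where(sd == 0.0, 1.0, sd)


def _one_over_f_noise(white: np.ndarray) -> np.ndarray:
    """Unit-variance noise rows with power spectral density ∝ 1/f."""
    n = white.shape[-1]
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n, d=1.0)
    f[0] = f[1]
    x = np.fft.irfft(spec / np.sqrt(f), n=n, axis=-1)
    x -= x.mean(axis=-1, keepdims=True)
    return x / x.std(axis=-1, keepdims=True)


def _gaussian_corr_for_lognormal(r: float, sigma: float) -> float:
    """Gaussian correlation whose exp(σz) log-normals correlate at ``r``."""
    if r <= 0.0:
        return 0.0
    s2 = sigma**2
    return float(np.log(1.0 + r * (np.exp(s2) - 1.0)) / s2)


def _bfs_parents(topology: frozenset[tuple[int, int]], n: int) -> list[tuple[int, int]]:
    """(child, parent) pairs in BFS order from the lowest-index root."""
    adj: dict[int, list[int]] = {i: [] for i in range(n)}
    for a, b in sorted(topology):
        adj[a].append(b)
        adj[b].append(a)
    order, seen, queue = [], {0}, [0]
    while queue:
        u = queue.pop(0)
        for v in sorted(adj[u]):
            if v not in seen:
                seen.add(v)
                order.append((v, u))
                queue.append(v)
    return order


def derive_subject_seed(cohort_seed: int, group_index: int, subject_index: int) -> int:
    """Deterministic, collision-resistant per-subject seed (< 2^31)."""
    ss = np.random.SeedSequence([int(cohort_seed), int(group_index), int(subject_index)])
    return int(ss.generate_state(1)[0]) & 0x7FFFFFFF


def simulate_subject(
    spec: CouplingSpec,
    cohort: CohortSpec,
    subject_seed: int,
    subject_id: str | None = None,
) -> Recording:
    """Simulate one subject's channels x samples recording (µV).

    Coupled components propagate along the tree from the lowest-index root:
    each child's analytic carrier is ``k·e^{-iΔ}`` times its parent's plus an
    independent remainder (re-normalized to constant envelope, which
    preserves phase), and each child's log-modulator is an AR blend of its
    parent's calibrated to the envelope-correlation target. Zero-lag leakage
    then mixes montage-adjacent channels, and 1/f noise is added per channel
    at the requested SNR. Deterministic for a fixed seed.
    """
    spec.band.validate_against_fs(cohort.fs)
    n_ch = len(cohort.montage)
    _validate_tree(spec.topology, n_ch)
    n = cohort.total_samples
    rng = np.random.default_rng(subject_seed)

    base = _narrowband_unit_envelope(rng.standard_normal((n_ch, n)), spec.band, cohort.fs)
    gauss = _slow_gaussian(rng.standard_normal((n_ch, n)), cohort.fs)
    noise = _one_over_f_noise(rng.standard_normal((n_ch, n)))

    k = spec.phase_coupling_strength
    rot = np.exp(-1j * spec.phase_lag)
    rho_g = _gaussian_corr_for_lognormal(spec.envelope_correlation, _MODULATOR_SIGMA)

    carriers: list[np.ndarray | None] = [None] * n_ch
    mods: list[np.ndarray | None] = [None] * n_ch
    carriers[0] = base[0]
    mods[0] = gauss[0]
    for child, parent in _bfs_parents(spec.topology, n_ch):
        mix = k * carriers[parent] * rot + math.sqrt(1.0 - k**2) * base[child]
        carriers[child] = mix / np.abs(mix) if k > 0.0 else base[child]
        mods[child] = rho_g * mods[parent] + math.sqrt(1.0 - rho_g**2) * gauss[child]

    sources = np.empty((n_ch, n))
    for c in range(n_ch):
        s = np.exp(_MODULATOR_SIGMA * mods[c]) * carriers[c].real
        sources[c] = (s - s.mean()) / s.std()

    if spec.leakage_mix > 0.0:
        mixed = sources.copy()
        mixed[1:] += spec.leakage_mix * sources[:-1]
        mixed[:-1] += spec.leakage_mix * sources[1:]
    else:
        mixed = sources

    data = mixed + noise * (mixed.std(axis=1, keepdims=True) / math.sqrt(spec.snr))
    return Recording(
        subject_id=subject_id or f"subj-{subject_seed}",
        channel_labels=cohort.montage,
        fs=cohort.fs,
        data=data * _OUTPUT_SCALE_UV,
    )


def simulate_subject_sources(
    spec: CouplingSpec, cohort: CohortSpec, subject_seed: int
) -> np.ndarray:
    """The coupled source matrix before leakage mixing and noise.

    Reproduces exactly the sources used by :func:`simulate_subject` for the
    same seed; exposed so coupling fidelity (spectral content, envelope
    correlation) can be verified on the clean components.
    """
    quiet = CouplingSpec(
        topology=spec.topology, band=spec.band, phase_lag=spec.phase_lag,
        phase_coupling_strength=spec.phase_coupling_strength,
        envelope_correlation=spec.envelope_correlation,
        leakage_mix=0.0, snr=1e12,
    )
    return simulate_subject(quiet, cohort, subject_seed).data / _OUTPUT_SCALE_UV


def simulate_cohort(
    cohort: CohortSpec, out_dir=None
) -> dict[str, list[Recording]]:
    """Simulate every subject of every group; optionally write ascii files.

    Subject seeds derive deterministically from (cohort seed, group index,
    subject index), so any subject can be regenerated in isolation. With
    ``out_dir`` set, recordings are written as
    ``<out_dir>/<group>/<subject_id>.txt`` in the ascii dialect.
    """
    from pathlib import Path

    from .io import write_recording

    out: dict[str, list[Recording]] = {}
    for gi, (label, spec) in enumerate(cohort.groups):
        recs = []
        for si in range(cohort.n_subjects):
            seed = derive_subject_seed(cohort.seed, gi, si)
            rec = simulate_subject(spec, cohort, seed, subject_id=f"{label}-{si:03d}")
            recs.append(rec)
        out[label] = recs
        if out_dir is not None:
            gdir = Path(out_dir) / label
            gdir.mkdir(parents=True, exist_ok=True)
            for rec in recs:
                write_recording(rec, gdir / f"{rec.subject_id}.txt")
    return out
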