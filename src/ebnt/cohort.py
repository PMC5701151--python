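"""Synthetic two-group multichannel cohorts with known phase coupling.

The generator produces the ground truth every downstream stage is
validated against: band-limited oscillations shared between chosen
channel pairs with a *consistent non-zero time lag* — precisely the
condition the phase lag index (PLI) detects — embedded in independent
broadband noise.  A two-group design multiplies the coupling strength
in selected bands by a reduction factor for group 2, emulating a cohort
in which one group has weakened band-specific connectivity.

Model
-----
Each channel owns one carrier per configured band: white noise
band-passed to the band and standardized.  A cohort-level *layout*
(identical for all subjects, drawn once from the seed) selects coupled
channel pairs with probability proportional to the product of the two
channels' "hubness" weights ``h_i h_j`` where ``log h ~ Normal(0,
hub_concentration^2)``; cortical functional networks are hub-dominated,
and the degree heterogeneity this induces is what gives the spanning
tree of the intact network its star-like, high-leaf-fraction backbone.
Each coupled pair is directed from its higher-hubness end: the target's
band component becomes

    c_target(t) + s * u_e * c_source(t - delta_e),

standardized to unit variance, where ``s`` is the band's coupling
strength (times the group-2 reduction factor where configured), ``u_e``
a per-edge strength multiplier and ``delta_e`` a per-edge lag drawn
around the configured phase lag.  A constant time shift yields a phase
difference of constant sign across the band, so the pair's PLI grows
monotonically with ``s``; the per-edge lag jitter keeps co-targets of
one hub at non-zero *relative* lags, so indirect coupling also registers
as (weaker) PLI instead of invisible zero-lag crosstalk.  All channels
additionally receive independent Gaussian broadband noise.

The configured phase lag must not be congruent to 0 mod pi: PLI is
blind to zero-lag (and anti-phase) coupling by construction, so such a
configuration would inject coupling the pipeline cannot verify.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.stats import norm

from .bands import BandDefinition, band_by_name
from .preprocess import _filtfilt, _fir_taps
from .recording import Recording

__all__ = ["BandCoupling", "CohortConfig", "BandLayout", "cohort_layout",
           "coupled_pairs", "generate_cohort"]


@dataclass(frozen=True)
class BandCoupling:
    """Coupling parameters for one band.

    strength
        Mixing coefficient in [0, 1]; 0 means independent channels.
    phase_lag
        Central lag in radians at the band center; must not be
        congruent to 0 mod pi when strength > 0.  Individual edges jitter
        around it (see :class:`CohortConfig.lag_jitter`).
    fraction_of_pairs
        Fraction of all channel pairs that are coupled, in [0, 1].
    """

    strength: float
    phase_lag: float
    fraction_of_pairs: float

    def __post_init__(self) -> None:
        if not 0 <= self.strength <= 1:
            raise ValueError("coupling strength must be in [0, 1]")
        if not 0 <= self.fraction_of_pairs <= 1:
            raise ValueError("fraction_of_pairs must be in [0, 1]")
        if self.strength > 0 and self.fraction_of_pairs > 0:
            residue = abs(self.phase_lag) % math.pi
            if min(residue, math.pi - residue) < 1e-9:
                raise ValueError(
                    "phase_lag congruent to 0 mod pi: the phase lag index "
                    "cannot detect zero-lag or anti-phase coupling, so this "
                    "coupling would be unverifiable")


@dataclass
class CohortConfig:
    """Full description of a synthetic two-group cohort.

    ``band_coupling`` maps band name -> :class:`BandCoupling`;
    ``group_effect`` maps band name -> multiplicative reduction in
    (0, 1] applied to group-2 coupling strengths.

    ``hub_concentration`` is the standard deviation of the log-normal
    channel hubness distribution steering pair selection (0 recovers a
    uniform layout); ``strength_jitter`` and ``lag_jitter`` are the
    (low, high) ranges of the per-edge uniform multipliers on coupling
    strength and phase lag.
    """

    n_subjects_per_group: int
    duration: float
    n_channels: int = 128
    sample_rate: float = 250.0
    band_coupling: dict[str, BandCoupling] = field(default_factory=dict)
    group_effect: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 1.0
    seed: int = 0
    hub_concentration: float = 1.5
    strength_jitter: tuple[float, float] = (1 / 3, 1.0)
    lag_jitter: tuple[float, float] = (0.5, 1.5)

    def __post_init__(self) -> None:
        if self.n_subjects_per_group < 1:
            raise ValueError("need at least one subject per group")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.n_channels < 2:
            raise ValueError("need at least two channels")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.hub_concentration < 0:
            raise ValueError("hub_concentration must be nonnegative")
        for pair_name, rng_pair in (("strength_jitter", self.strength_jitter),
                                    ("lag_jitter", self.lag_jitter)):
            lo, hi = rng_pair
            if not 0 < lo <= hi:
                raise ValueError(f"{pair_name} must satisfy 0 < low <= high")
        for name, cpl in self.band_coupling.items():
            band_by_name(name)  # validates the label
            if not isinstance(cpl, BandCoupling):
                raise TypeError(
                    f"band_coupling[{name!r}] must be a BandCoupling")
            if cpl.strength > 0 and cpl.fraction_of_pairs > 0:
                worst = abs(cpl.phase_lag) * self.lag_jitter[1]
                if worst >= math.pi:
                    raise ValueError(
                        f"band {name!r}: lag jitter can reach {worst:.2f} "
                        "rad >= pi; reduce phase_lag or lag_jitter")
        for name, factor in self.group_effect.items():
            if not 0 < factor <= 1:
                raise ValueError(f"group_effect[{name!r}] must be in (0, 1]")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sample_rate))


@dataclass
class BandLayout:
    """Cohort-level ground truth of one band's coupling structure."""

    #: (source, target) per coupled pair; source is the higher-hubness end
    directed_pairs: list[tuple[int, int]]
    #: per-edge strength multipliers (same order as directed_pairs)
    strength_factors: np.ndarray
    #: per-edge lags in samples (sign follows the configured phase lag)
    lag_samples: np.ndarray
    #: channel hubness weights used for pair selection
    hubness: np.ndarray

    @property
    def pairs(self) -> list[tuple[int, int]]:
        """Undirected coupled pairs, sorted."""
        return sorted(tuple(sorted(p)) for p in self.directed_pairs)


def _rngs(config: CohortConfig) -> tuple[np.random.Generator,
                                         np.random.Generator]:
    """One stream for the cohort-level layout, one for signal data, both
    derived from the single cohort seed."""
    layout_ss, data_ss = np.random.SeedSequence(config.seed).spawn(2)
    return np.random.default_rng(layout_ss), np.random.default_rng(data_ss)


def _lag_to_samples(band: BandDefinition, lag: float, fs: float) -> int:
    delta = int(round(lag / (2 * math.pi * band.center) * fs))
    if delta == 0 and lag != 0:
        delta = 1 if lag > 0 else -1  # never collapse to zero-lag
    return delta


def cohort_layout(config: CohortConfig) -> dict[str, BandLayout]:
    """The per-band coupling layout implied by the config (and nothing
    else): reproducible ground truth for tests and recovery checks."""
    layout_rng, _ = _rngs(config)
    all_pairs = list(combinations(range(config.n_channels), 2))
    layout: dict[str, BandLayout] = {}
    # deterministic heavy-tailed hubness profile (log-normal quantiles):
    # the degree heterogeneity of the coupled subgraph is a designed
    # property of the cohort, not left to a per-seed draw
    n = config.n_channels
    quantiles = norm.ppf((np.arange(n) + 0.5) / n)
    profile = np.exp(config.hub_concentration * quantiles)
    for name, cpl in config.band_coupling.items():
        band = band_by_name(name)
        # random assignment of the profile to channels, per band
        hubness = profile[layout_rng.permutation(n)]
        probs = np.array([hubness[i] * hubness[j] for i, j in all_pairs])
        probs /= probs.sum()
        n_coupled = int(round(cpl.fraction_of_pairs * len(all_pairs)))
        chosen = layout_rng.choice(len(all_pairs), size=n_coupled,
                                   replace=False, p=probs)
        directed = [(i, j) if hubness[i] >= hubness[j] else (j, i)
                    for i, j in (all_pairs[k] for k in chosen)]
        factors = layout_rng.uniform(*config.strength_jitter, size=n_coupled)
        lag_mult = layout_rng.uniform(*config.lag_jitter, size=n_coupled)
        lags = np.array([
            _lag_to_samples(band, m * cpl.phase_lag, config.sample_rate)
            for m in lag_mult], dtype=int)
        layout[name] = BandLayout(
            directed_pairs=directed,
            strength_factors=factors,
            lag_samples=lags,
            hubness=hubness,
        )
    return layout


def coupled_pairs(config: CohortConfig) -> dict[str, list[tuple[int, int]]]:
    """Undirected ground-truth coupled channel pairs per band."""
    return {name: bl.pairs for name, bl in cohort_layout(config).items()}


def _carrier(rng: np.random.Generator, n: int, taps: np.ndarray) -> np.ndarray:
    """Unit-variance band-limited noise of length n."""
    raw = rng.standard_normal(n)
    out = _filtfilt(taps, raw)
    sd = out.std()
    return out / sd if sd > 0 else out


def _band_component(rng: np.random.Generator, config: CohortConfig,
                    bl: BandLayout, taps: np.ndarray,
                    strength: float) -> np.ndarray:
    """One subject's standardized band component for one band."""
    n = config.n_samples
    dmax = int(np.abs(bl.lag_samples).max(initial=0))
    carriers = [_carrier(rng, n + 2 * dmax, taps)
                for _ in range(config.n_channels)]
    comp = np.stack([c[dmax:dmax + n] for c in carriers])
    for (src, tgt), u, d in zip(bl.directed_pairs, bl.strength_factors,
                                bl.lag_samples):
        comp[tgt] = comp[tgt] + strength * u \
            * carriers[src][dmax - d:dmax - d + n]
    sd = comp.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return comp / sd


def generate_cohort(config: CohortConfig) -> list[Recording]:
    """Generate the full two-group cohort.

    Deterministic given the config (including seed).  Group-1 subjects
    come first, then group 2; subject ids encode the group.
    """
    layout = cohort_layout(config)
    _, data_rng = _rngs(config)
    fs, n = config.sample_rate, config.n_samples

    band_info = []
    for name, cpl in config.band_coupling.items():
        band = band_by_name(name)
        taps = _fir_taps(fs, [band.low, band.high], pass_zero=False,
                         transition=0.25 * band.low)
        band_info.append((name, cpl, taps))

    recordings: list[Recording] = []
    width = len(str(config.n_subjects_per_group))
    for group in (1, 2):
        for s in range(config.n_subjects_per_group):
            data = config.noise_sd * data_rng.standard_normal(
                (config.n_channels, n))
            for name, cpl, taps in band_info:
                strength = cpl.strength
                if group == 2:
                    strength *= config.group_effect.get(name, 1.0)
                data += _band_component(data_rng, config, layout[name],
                                        taps, strength)
            recordings.append(Recording(
                subject_id=f"g{group}_s{s + 1:0{width}d}",
                data=data,
                sample_rate=fs,
                group=group,
            ))
    return recordings
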