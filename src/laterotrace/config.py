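"""Simulation and pipeline configuration objects.

Defaults mirror the experimental design the simulator emulates: depth
multi-unit recordings use 10 song stimuli x 25 shuffled repetitions with an
8 s inter-stimulus interval; epidural sessions use 3 call stimuli x 100
repetitions at 5 s ISI on an 8-pin array (2 pins per hemisphere x
caudal/rostral quadrant); operant training runs 50-trial Go/NoGo blocks with
a 50/50 Go assignment until an 80% criterion on two consecutive blocks or 21
days.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic bilateral recording generator.

    Attributes
    ----------
    seed
        Master seed; every session derives an independent stream from it.
    sample_rate
        Hz. Depth recordings are band-passed 0.5-5 kHz in hardware, epidural
        potentials 1-1000 Hz; the generator's traces are already "filtered"
        so a modest default keeps arrays small.
    baseline_noise_rms
        Background noise RMS sigma_b, volts.
    evoked_amplitude
        Base evoked RMS amplitude A, volts (per-site gain before hemispheric
        and adaptation scaling).
    adaptation_fraction
        Fractional per-repetition decrement k: presentation t of a stimulus
        has evoked RMS proportional to ``(1 - k)**(t - 1)``. For small k the
        normalized adaptation rate recovered downstream is ~ -k.
    non_adapting_site_fraction
        Proportion of channels generated with k = 0 (Field-L-like sites that
        the adaptation filter should reject).
    erp_caudal_gain
        Evoked-gain ratio of caudal over rostral pins in epidural sessions.
    pre_onset / post_offset
        Silence padding before stimulus onset and after the response window,
        seconds. ``pre_onset`` must cover the 0.5 s control period.
    """

    seed: int = 0
    sample_rate: float = 10_000.0
    baseline_noise_rms: float = 5e-6
    evoked_amplitude: float = 2e-5
    adaptation_fraction: float = 0.10
    n_channels_per_hemisphere: int = 8
    n_stimuli: int = 10
    n_presentations: int = 25
    stimulus_duration: float = 1.0
    isi: float = 8.0
    non_adapting_site_fraction: float = 0.11
    erp_caudal_gain: float = 2.0
    pre_onset: float = 0.6
    post_offset: float = 0.05

    def validate(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError(f"sample_rate must be positive, got {self.sample_rate}")
        if self.baseline_noise_rms < 0:
            raise ValueError("baseline_noise_rms must be >= 0")
        if self.evoked_amplitude < 0:
            raise ValueError("evoked_amplitude must be >= 0")
        if not 0 <= self.adaptation_fraction < 1:
            raise ValueError("adaptation_fraction must be in [0, 1)")
        if not 0 <= self.non_adapting_site_fraction <= 1:
            raise ValueError("non_adapting_site_fraction must be in [0, 1]")
        if self.pre_onset < 0.5:
            raise ValueError("pre_onset must cover the 0.5 s control period")
        if min(self.n_channels_per_hemisphere, self.n_stimuli, self.n_presentations) < 1:
            raise ValueError("counts must be >= 1")
        if self.stimulus_duration <= 0:
            raise ValueError("stimulus_duration must be positive")


@dataclass(frozen=True)
class LateralizationProfile:
    """Ground-truth hemispheric gain time course for one exposure condition.

    ``breakpoints`` maps inclusive day ranges to the right/left evoked gain
    ratio g; the ranges must tile the exposure span without overlap. Days
    before exposure onset (day < 0) are the silent baseline and always carry
    g = 1 (no lateral bias), matching the attenuated-baseline observation.
    """

    condition: str
    breakpoints: tuple[tuple[tuple[int, int], float], ...]

    def __post_init__(self) -> None:
        covered: list[int] = []
        for (lo, hi), g in self.breakpoints:
            if lo > hi:
                raise ValueError(f"invalid day range ({lo}, {hi})")
            if g <= 0:
                raise ValueError(f"gain ratio must be positive, got {g}")
            covered.extend(range(lo, hi + 1))
        if len(covered) != len(set(covered)):
            raise ValueError("day ranges overlap")

    @property
    def span(self) -> tuple[int, int]:
        days = [d for (lo, hi), _ in self.breakpoints for d in (lo, hi)]
        return (min(days), max(days))

    def gain(self, day: int) -> float:
        """Right/left gain ratio on ``day``; baseline days (< 0) return 1."""
        if day < 0:
            return 1.0
        for (lo, hi), g in self.breakpoints:
            if lo <= day <= hi:
                return g
        raise ValueError(
            f"day {day} outside profile span {self.span} for condition {self.condition!r}"
        )


def default_profiles() -> dict[str, LateralizationProfile]:
    """Stated-world gain profiles over a 21-day exposure (days 0-20).

    * ``Con-Env``: constant right bias (typical pattern maintained by a
      familiar conspecific environment).
    * ``Het-Env``: no bias on days 0-5, reversal (left bias, g < 1) on days
      6-14, return to right bias on days 15-20.
    * ``Silence``: g = 1 throughout (lateralization abolished).
    """
    return {
        "Con-Env": LateralizationProfile("Con-Env", (((0, 20), 1.3),)),
        "Het-Env": LateralizationProfile(
            "Het-Env", (((0, 5), 1.0), ((6, 14), 0.7), ((15, 20), 1.4))
        ),
        "Silence": LateralizationProfile("Silence", (((0, 20), 1.0),)),
    }


@dataclass(frozen=True)
class BehaviorSimConfig:
    """Bernoulli learner for the operant Go/NoGo simulation.

    P(correct) on training day d (0-based) follows a saturating exponential
    ``asymptote - (asymptote - p_correct_initial) * exp(-learning_rate * d)``.
    ``go_probability`` is enforced as exact 25/25 balance within each
    50-trial block unless ``iid_assignment`` is set.
    """

    seed: int = 0
    p_correct_initial: float = 0.5
    learning_rate: float = 0.12
    asymptote: float = 0.95
    n_trials_per_day: int = 100
    go_probability: float = 0.5
    block_size: int = 50
    iid_assignment: bool = False

    def validate(self) -> None:
        for name in ("p_correct_initial", "asymptote", "go_probability"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.asymptote < self.p_correct_initial:
            raise ValueError("asymptote must be >= p_correct_initial")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.n_trials_per_day < 1 or self.block_size < 1:
            raise ValueError("trial counts must be >= 1")

    def p_correct(self, day: int) -> float:
        import math

        return self.asymptote - (self.asymptote - self.p_correct_initial) * math.exp(
            -self.learning_rate * day
        )


# analysis constants with the values printed in the source protocol
@dataclass(frozen=True)
class AnalysisParams:
    """All tunable analysis constants, with their protocol values as defaults."""

    baseline_window_s: float = 0.5          # control period before onset
    stimulus_offset_s: float = 0.1          # response window extension past offset
    early_trials: tuple[int, int] = (2, 6)  # ARM averaging window (inclusive)
    adr_trials: tuple[int, int] = (6, 25)   # regression window (inclusive)
    adr_criterion: float = -0.05            # site kept iff AdR < criterion (strict)
    site_rule: str = "mean"                 # per-site aggregation of AdR over stimuli
    earm_max_trials: int = 25               # trials averaged for the stable ERP
    bin_width_days: int = 3
    criterion_threshold: float = 0.8
    criterion_blocks: int = 2
    block_size: int = 50
    max_training_days: int = 21
    channel_selection: str = "all"          # or "caudal_only" for epidural LI
    alpha: float = 0.05


@dataclass
class PipelineConfig:
    """End-to-end demo pipeline configuration (simulate -> ... -> stats).

    The default scale is deliberately reduced relative to the emulated
    experiment (fewer subjects, presentations and samples) so the pipeline
    completes in well under a minute; the analysis constants keep their
    protocol values via :class:`AnalysisParams`.
    """

    seed: int = 0
    conditions: tuple[str, ...] = ("Con-Env", "Het-Env")
    n_subjects_per_condition: int = 3
    baseline_days: tuple[int, ...] = (-4, -3, -2, -1)
    exposure_days: tuple[int, ...] = tuple(range(0, 21, 2))
    mua_day: int = 9
    erp_sim: SimConfig = field(default_factory=lambda: SimConfig(
        sample_rate=2000.0, n_stimuli=3, n_presentations=25,
        stimulus_duration=0.25, isi=5.0, baseline_noise_rms=6e-6,
        evoked_amplitude=2e-5, adaptation_fraction=0.0,
        non_adapting_site_fraction=0.0,
    ))
    mua_sim: SimConfig = field(default_factory=lambda: SimConfig(
        sample_rate=2000.0, n_stimuli=4, n_presentations=25,
        stimulus_duration=0.3, isi=8.0, n_channels_per_hemisphere=8,
    ))
    behavior_sim: BehaviorSimConfig = field(default_factory=BehaviorSimConfig)
    n_behavior_subjects: int = 5
    behavior_training_days: int = 21
    params: AnalysisParams = field(default_factory=AnalysisParams)

    def to_dict(self) -> dict:
        return asdict(self)
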