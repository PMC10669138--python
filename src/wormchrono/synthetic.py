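"""Synthetic COPAS-like worm populations with known ground truth.

The generator emulates the statistical structure the chronogram analysis
assumes in a mixed-stage *C. elegans* population carrying a gonad-localized
GFP reporter:

* worm "length" (profile sample count, with TOF set equal to it) follows a
  log-normal distribution covering L1 larvae through adults;
* the longitudinal green profile is a flat autofluorescence baseline plus a
  narrow anterior bump (pharyngeal autofluorescence — the anteroposterior
  asymmetry that makes head/tail orientation recoverable) and, above a
  length threshold corresponding to the L3/L4 transition, a broad
  gonad-localized Gaussian bump;
* each worm transits the flow cell head- or tail-first at random, so its
  emitted profile may be reversed;
* targeted irradiation of the gonad primordium is modeled as a growth delay
  (shift of the log-length mean) plus a reduction — or, for an agenesis
  fraction, complete loss — of the gonadal signal amplitude;
* instrument artifacts are appended: bubbles (tiny TOF, disproportionate
  EXT) and eggs/debris (profiles shorter than any real worm).

Every draw comes from one seeded :class:`numpy.random.Generator` (PCG64),
so identical configs produce identical populations across runs and
platforms. A per-event ground-truth table makes each pipeline stage
testable against known answers.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .copas_io import EventRecord, PopulationDataset, ProfileRecord

#: relative body position of the anterior (pharyngeal) marker
HEAD_CENTER = 0.15
#: width (fraction of body length) of the anterior marker bump
HEAD_WIDTH = 0.05

GROUND_TRUTH_COLUMNS = [
    "event_id", "true_length", "true_gonad_amplitude", "was_flipped", "is_artifact",
]


@dataclass(frozen=True)
class PopulationConfig:
    """Generative parameters for one population (one condition).

    Lengths are in profile-sample units (TOF is set equal to the sample
    count); intensities are in PMT units. The defaults describe an
    unirradiated mixed-stage population; :meth:`irradiated` applies the
    irradiation effect model on top.
    """

    n_worms: int = 500
    length_log_mean: float = 5.5
    length_log_sd: float = 0.45
    gonad_onset_length: float = 250.0
    gonad_center: float = 0.55
    gonad_width: float = 0.08
    gonad_amplitude: float = 800.0
    gonad_ramp_length: float = 50.0
    head_marker_amplitude: float = 20.0
    baseline: float = 5.0
    noise_sd: float = 3.0
    irradiation_growth_delay: float = 0.0
    gonad_reduction: float = 1.0
    agenesis_fraction: float = 0.0
    flip_probability: float = 0.5
    bubble_rate: float = 0.0
    debris_rate: float = 0.0
    ext_per_length: float = 0.5
    ext_noise_sd: float = 0.05
    condition_label: str = "control"
    seed: int = 0

    def __post_init__(self):
        if self.n_worms < 0:
            raise ValueError("n_worms must be >= 0")
        for name in ("gonad_amplitude", "head_marker_amplitude", "baseline",
                     "noise_sd", "irradiation_growth_delay", "ext_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("gonad_reduction", "agenesis_fraction", "flip_probability",
                     "bubble_rate", "debris_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0 < self.gonad_center < 1:
            raise ValueError("gonad_center must be in (0, 1)")

    @classmethod
    def control(cls, n_worms: int = 500, seed: int = 0, **kw) -> "PopulationConfig":
        return cls(n_worms=n_worms, seed=seed, condition_label="control", **kw)

    @classmethod
    def irradiated(
        cls,
        n_worms: int = 500,
        seed: int = 0,
        growth_delay: float = 0.3,
        gonad_reduction: float = 0.3,
        agenesis_fraction: float = 0.0,
        **kw,
    ) -> "PopulationConfig":
        """Condition emulating a 300 Gy targeted gonad-primordium irradiation:
        stunted growth plus reduced (or absent) gonadal GFP."""
        return cls(
            n_worms=n_worms,
            seed=seed,
            irradiation_growth_delay=growth_delay,
            gonad_reduction=gonad_reduction,
            agenesis_fraction=agenesis_fraction,
            condition_label="irradiated-300Gy",
            **kw,
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True), encoding="utf-8")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PopulationConfig":
        return cls(**yaml.safe_load(Path(path).read_text(encoding="utf-8")))


def _bump(x: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((x - center) / width) ** 2)


def gonad_growth_factor(length: int, config: PopulationConfig) -> float:
    """Developmental scaling of the gonadal signal: zero at or below the onset
    length, then ramping linearly to full amplitude over ``gonad_ramp_length``
    samples (the gonad grows with the worm rather than switching on)."""
    if length <= config.gonad_onset_length:
        return 0.0
    if config.gonad_ramp_length <= 0:
        return 1.0
    return float(min(1.0, (length - config.gonad_onset_length) / config.gonad_ramp_length))


def true_profile(
    length: int, config: PopulationConfig, gonad_amplitude: float | None = None
) -> np.ndarray:
    """Noise-free longitudinal profile of a worm of ``length`` samples, head at
    index 0. The gonadal bump is present only for worms longer than the
    onset threshold (L3/L4 and above), ramping in with length."""
    if length < 2:
        raise ValueError(f"profile length must be >= 2, got {length}")
    amp = config.gonad_amplitude if gonad_amplitude is None else gonad_amplitude
    x = np.linspace(0.0, 1.0, length)
    prof = np.full(length, config.baseline, dtype=float)
    prof += config.head_marker_amplitude * _bump(x, HEAD_CENTER, HEAD_WIDTH)
    factor = gonad_growth_factor(length, config)
    if factor > 0.0:
        prof += amp * factor * _bump(x, config.gonad_center, config.gonad_width)
    return prof


def expected_worm_mean(length: int, config: PopulationConfig,
                       gonad_amplitude: float | None = None) -> float:
    """Mean of the noise-free profile — the oracle for effect-recovery tests."""
    return float(true_profile(length, config, gonad_amplitude).mean())


def _worm_event(rng: np.random.Generator, event_id: str, length: int,
                amp: float, config: PopulationConfig):
    prof = true_profile(length, config, gonad_amplitude=amp)
    if config.noise_sd > 0:
        prof = np.clip(prof + rng.normal(0.0, config.noise_sd, size=length), 0.0, None)
    flipped = bool(rng.random() < config.flip_probability)
    if flipped:
        prof = prof[::-1].copy()
    ext = max(0.0, config.ext_per_length * length * (1.0 + rng.normal(0.0, config.ext_noise_sd)))
    event = EventRecord(event_id=event_id, tof=float(length), ext=ext,
                        ph_green=float(prof.max()))
    return event, ProfileRecord(event_id=event_id, samples=prof), flipped


def simulate_population(config: PopulationConfig) -> tuple[PopulationDataset, pd.DataFrame]:
    """Draw a full population: worms, then injected artifacts, plus the
    per-event ground-truth table (one row per emitted event)."""
    rng = np.random.default_rng(config.seed)
    events: list[EventRecord] = []
    profiles: dict[str, ProfileRecord] = {}
    truth_rows: list[dict] = []

    lengths = np.maximum(
        2,
        np.rint(rng.lognormal(
            mean=config.length_log_mean - config.irradiation_growth_delay,
            sigma=config.length_log_sd,
            size=config.n_worms,
        )).astype(int),
    )
    agenesis = rng.random(config.n_worms) < config.agenesis_fraction
    for i in range(config.n_worms):
        amp = 0.0 if agenesis[i] else config.gonad_amplitude * config.gonad_reduction
        event_id = f"w{i + 1:05d}"
        event, profile, flipped = _worm_event(rng, event_id, int(lengths[i]), amp, config)
        events.append(event)
        profiles[event_id] = profile
        truth_rows.append({
            "event_id": event_id,
            "true_length": int(lengths[i]),
            "true_gonad_amplitude": amp,
            "was_flipped": flipped,
            "is_artifact": False,
        })

    dataset = PopulationDataset(
        condition_label=config.condition_label,
        events=events,
        profiles=profiles,
        metadata={"generator": "wormchrono.synthetic", "seed": str(config.seed)},
    )
    dataset, artifact_truth = inject_artifacts(dataset, config, rng=rng)
    truth = pd.DataFrame(truth_rows + artifact_truth, columns=GROUND_TRUTH_COLUMNS)
    return dataset, truth


def inject_artifacts(
    dataset: PopulationDataset,
    config: PopulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[PopulationDataset, list[dict]]:
    """Append flagged artifact events; original records are untouched.

    Bubbles: TOF < 30 with EXT far above the optical density of any worm of
    that length. Eggs/debris: profiles of 10–79 samples, below the
    short-profile filter threshold. Counts are binomial in ``n_worms``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    events = list(dataset.events)
    profiles = dict(dataset.profiles)
    truth_rows: list[dict] = []

    n_bubbles = int(rng.binomial(config.n_worms, config.bubble_rate)) if config.bubble_rate else 0
    n_debris = int(rng.binomial(config.n_worms, config.debris_rate)) if config.debris_rate else 0

    for i in range(n_bubbles):
        event_id = f"bub{i + 1:04d}"
        tof = float(rng.uniform(5.0, 25.0))
        ext = tof * float(rng.uniform(20.0, 50.0))  # EXT/TOF far above any worm
        length = max(2, int(round(tof)))
        samples = np.clip(
            config.baseline + rng.normal(0.0, config.noise_sd, size=length), 0.0, None)
        events.append(EventRecord(event_id=event_id, tof=tof, ext=ext,
                                  ph_green=float(samples.max())))
        profiles[event_id] = ProfileRecord(event_id=event_id, samples=samples)
        truth_rows.append({"event_id": event_id, "true_length": length,
                           "true_gonad_amplitude": 0.0, "was_flipped": False,
                           "is_artifact": True})
    for i in range(n_debris):
        event_id = f"deb{i + 1:04d}"
        length = int(rng.integers(10, 80))  # always below the length-80 filter
        samples = np.clip(
            config.baseline + rng.normal(0.0, config.noise_sd, size=length), 0.0, None)
        ext = max(0.0, config.ext_per_length * length
                  * (1.0 + rng.normal(0.0, config.ext_noise_sd)))
        events.append(EventRecord(event_id=event_id, tof=float(length), ext=ext,
                                  ph_green=float(samples.max())))
        profiles[event_id] = ProfileRecord(event_id=event_id, samples=samples)
        truth_rows.append({"event_id": event_id, "true_length": length,
                           "true_gonad_amplitude": 0.0, "was_flipped": False,
                           "is_artifact": True})

    out = PopulationDataset(
        condition_label=dataset.condition_label,
        events=events,
        profiles=profiles,
        metadata=dict(dataset.metadata),
    )
    return out, truth_rows


def write_ground_truth(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def paired_conditions(
    n_control: int,
    n_irradiated: int,
    seed: int,
    growth_delay: float = 0.3,
    gonad_reduction: float = 0.3,
    **kw,
) -> tuple[PopulationDataset, PopulationDataset]:
    """Convenience: a control and an irradiated population with decorrelated
    seeds derived from one master seed."""
    ss = np.random.SeedSequence(seed).spawn(2)
    c_seed, i_seed = (int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss)
    control, _ = simulate_population(PopulationConfig.control(n_control, seed=c_seed, **kw))
    irradiated, _ = simulate_population(PopulationConfig.irradiated(
        n_irradiated, seed=i_seed, growth_delay=growth_delay,
        gonad_reduction=gonad_reduction, **kw))
    return control, irradiated
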