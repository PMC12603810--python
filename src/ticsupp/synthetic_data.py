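"""Synthetic cohorts for the tic/blink-suppression analysis pipeline.

The generator emulates the structure of a two-group pediatric study: a
typically developing control group (TDC, blink suppression) and a chronic
tic disorder group (CTD, tic suppression), each performing three 5-7 minute
block conditions (free tic/blink ``NoSupp``, verbal-instruction suppression
``Supp_Vrb``, rewarded suppression ``Supp_Rwd``).  Per subject it produces:

* covariates (age, sex, psychotropic-drug flag, premonitory-urge score) and
  a unit-variance latent "suppression ability";
* per-condition event trains from a refractory Poisson process whose rate
  under suppression decreases monotonically with ability;
* independent components (ICs): a 3-D dipole position drawn around one of
  13 spatial centroids, and pre-event epochs (-5..0 s) of pink noise plus
  narrow-band oscillations whose amplitude modulation follows a configurable
  effect specification per (group, condition).

All randomness flows from ``CohortConfig.seed``; a fixed seed reproduces the
cohort and every epoch bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "CONDITIONS",
    "SUPPRESSION_CONDITIONS",
    "GROUPS",
    "DEFAULT_EVENT_RATE",
    "DEFAULT_CENTROIDS",
    "EffectSpec",
    "CohortConfig",
    "EventSeries",
    "SubjectRecord",
    "CohortTable",
    "ICEpochSet",
    "generate_cohort",
    "simulate_ic_epochs",
    "simulate_cohort_ics",
    "simulate_summary_pairs",
    "write_fixture",
    "read_fixture",
]

CONDITIONS = ("NoSupp", "Supp_Vrb", "Supp_Rwd")
SUPPRESSION_CONDITIONS = ("Supp_Vrb", "Supp_Rwd")
GROUPS = ("TDC", "CTD")

#: group-mean events/min per condition; emulation targets for the cohort
DEFAULT_EVENT_RATE: dict[tuple[str, str], float] = {
    ("TDC", "NoSupp"): 17.9,
    ("TDC", "Supp_Vrb"): 11.0,
    ("TDC", "Supp_Rwd"): 8.6,
    ("CTD", "NoSupp"): 3.6,
    ("CTD", "Supp_Vrb"): 2.3,
    ("CTD", "Supp_Rwd"): 1.9,
}

#: between-subject log-normal sigma of the rate multiplier, per group;
#: chosen to emulate the groups' coefficient of variation in event rates
DEFAULT_RATE_DISPERSION: dict[str, float] = {"TDC": 0.5, "CTD": 0.8}

_AGE_MODEL = {"TDC": (9.6, 1.5, 8.0, 12.0), "CTD": (9.7, 1.6, 8.0, 14.0)}
_MALE_FRACTION = {"TDC": 19 / 37, "CTD": 27 / 39}
_DRUG_FRACTION = {"TDC": 0.0, "CTD": 9 / 39}
_PUTS_MODEL = {"CTD": (4.7, 2.3)}  # urge-score mean/SD; absent for TDC

#: 13 spatial centroids (role, (x, y, z) mm) spread over a +/-70 mm head volume
DEFAULT_CENTROIDS: tuple[tuple[str, tuple[float, float, float]], ...] = (
    ("mid_frontal_r", (32.0, 38.0, 28.0)),
    ("superior_frontal_l", (-20.0, 25.0, 50.0)),
    ("mid_cingulate", (2.0, -6.0, 38.0)),
    ("central_r", (40.0, -20.0, 50.0)),
    ("centro_temporal_l", (-55.0, -25.0, 15.0)),
    ("prefrontal_r", (35.0, 50.0, 5.0)),
    ("frontal_pole", (0.0, 60.0, 10.0)),
    ("temporal_r", (55.0, -30.0, 2.0)),
    ("parietal_l", (-40.0, -55.0, 45.0)),
    ("parietal_r", (40.0, -55.0, 45.0)),
    ("precuneus", (2.0, -65.0, 42.0)),
    ("occipital_l", (-25.0, -85.0, 8.0)),
    ("occipital_r", (25.0, -85.0, 8.0)),
)


@dataclass(frozen=True)
class EffectSpec:
    """One injected oscillatory power modulation.

    A carrier at the geometric centre of ``band_hz`` is present throughout
    every epoch; inside ``window_s`` its amplitude is multiplied so that the
    resulting spectral perturbation equals ``amplitude_db[(group, condition)]``
    dB (0 dB entries and unlisted cells leave the carrier unmodulated).  For
    suppression conditions the injected dB is further scaled by
    ``1 + coupling_beta * latent_ability``, tying the EEG modulation to the
    same latent that drives behavioural suppression.
    """

    band_hz: tuple[float, float]
    window_s: tuple[float, float]
    amplitude_db: dict[tuple[str, str], float]
    cluster_roles: tuple[str, ...] | None = None  # None = all spatial clusters

    def __post_init__(self):
        lo, hi = self.band_hz
        if not (1.0 <= lo < hi <= 50.0):
            raise ValueError("band must satisfy 1 <= lo < hi <= 50 Hz")
        t0, t1 = self.window_s
        if not (-5.0 <= t0 < t1 <= 0.0):
            raise ValueError("effect window must lie within [-5, 0] s")

    @property
    def carrier_hz(self) -> float:
        return float(np.sqrt(self.band_hz[0] * self.band_hz[1]))


def default_effect_spec() -> list[EffectSpec]:
    """Effects emulating the study-like pattern: a theta power increase under
    suppression in frontal/cingulate/central clusters for both groups, and a
    beta-band modulation of opposite sign between groups in centro-temporal
    sensorimotor clusters."""
    supp = SUPPRESSION_CONDITIONS
    theta = EffectSpec(
        band_hz=(4.0, 8.0),
        window_s=(-3.0, 0.0),
        amplitude_db={(g, c): 3.0 for g in GROUPS for c in supp},
        cluster_roles=("mid_frontal_r", "superior_frontal_l", "mid_cingulate", "central_r"),
    )
    sensorimotor = EffectSpec(
        band_hz=(13.0, 30.0),
        window_s=(-2.0, 0.0),
        amplitude_db={("TDC", c): 2.0 for c in supp} | {("CTD", c): -2.0 for c in supp},
        cluster_roles=("central_r", "centro_temporal_l"),
    )
    return [theta, sensorimotor]


@dataclass
class CohortConfig:
    """Study-condition parameters for the synthetic cohort."""

    n_per_group: dict[str, int] = field(default_factory=lambda: {"TDC": 37, "CTD": 39})
    block_duration_min: tuple[float, float] = (5.0, 7.0)
    event_rate: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_EVENT_RATE)
    )
    rate_dispersion: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RATE_DISPERSION)
    )
    condition_noise: float = 0.15  # log-normal sigma of condition-level rate noise
    refractory_s: float = 1.0
    sampling_rate: float = 250.0
    effect_spec: list[EffectSpec] = field(default_factory=default_effect_spec)
    coupling_beta: float = 0.5
    suppression_kappa: float = 0.3  # ability -> suppression-rate link strength
    n_spatial_clusters: int = 13
    centroid_sd_mm: float = 8.0
    ics_per_subject: tuple[int, int] = (2, 5)
    noise_sd: float = 0.3  # pink-noise RMS, arbitrary units
    carrier_amplitude: float = 1.0
    min_events: int = 15
    seed: int = 0

    def __post_init__(self):
        for g, n in self.n_per_group.items():
            if n <= 0:
                raise ValueError(f"non-positive group size for {g!r}")
        for key, r in self.event_rate.items():
            if r < 0:
                raise ValueError(f"negative event rate for {key!r}")
        lo, hi = self.block_duration_min
        if not (0 < lo <= hi):
            raise ValueError("invalid block duration range")
        if self.min_events < 0:
            raise ValueError("min_events must be >= 0")
        if self.n_spatial_clusters > len(DEFAULT_CENTROIDS):
            raise ValueError(
                f"at most {len(DEFAULT_CENTROIDS)} default spatial centroids are defined"
            )

    def centroids(self) -> list[tuple[str, np.ndarray]]:
        return [
            (role, np.asarray(xyz, dtype=float))
            for role, xyz in DEFAULT_CENTROIDS[: self.n_spatial_clusters]
        ]


@dataclass(frozen=True)
class EventSeries:
    """Annotated event (tic/blink) onsets within one block condition."""

    condition: str
    event_times_s: np.ndarray
    block_duration_s: float

    def __post_init__(self):
        times = np.asarray(self.event_times_s, dtype=float)
        if times.size and (np.any(np.diff(times) <= 0)):
            raise ValueError("event times must be strictly increasing")
        if times.size and (times[0] < 0 or times[-1] > self.block_duration_s):
            raise ValueError("event times must lie within the block")
        object.__setattr__(self, "event_times_s", times)

    @property
    def n_events(self) -> int:
        return int(self.event_times_s.size)


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    group: str
    age: float
    sex: str
    drug: bool
    puts_score: float
    latent_ability: float
    excluded: bool


@dataclass
class CohortTable:
    """Per-subject covariates plus all per-condition event series."""

    subjects: pd.DataFrame  # subject_id, group, age, sex, drug, puts, ability, excluded
    events: pd.DataFrame  # subject_id, condition, event_time_s, block_duration_s
    config: CohortConfig

    def event_series(self, subject_id: str, condition: str) -> EventSeries:
        sel = self.events[
            (self.events.subject_id == subject_id) & (self.events.condition == condition)
        ]
        if sel.empty:
            dur = self._duration_of(subject_id)
            return EventSeries(condition, np.empty(0), dur)
        return EventSeries(
            condition,
            sel.event_time_s.to_numpy(),
            float(sel.block_duration_s.iloc[0]),
        )

    def _duration_of(self, subject_id: str) -> float:
        sel = self.events[self.events.subject_id == subject_id]
        if sel.empty:
            return float(np.mean(self.config.block_duration_min)) * 60.0
        return float(sel.block_duration_s.iloc[0])

    def subject_record(self, subject_id: str) -> SubjectRecord:
        row = self.subjects.set_index("subject_id").loc[subject_id]
        return SubjectRecord(
            subject_id=subject_id,
            group=row.group,
            age=float(row.age),
            sex=row.sex,
            drug=bool(row.drug),
            puts_score=float(row.puts),
            latent_ability=float(row.latent_ability),
            excluded=bool(row.excluded),
        )

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def included(self) -> pd.DataFrame:
        return self.subjects[~self.subjects.excluded]


@dataclass(frozen=True)
class ICEpochSet:
    """One IC: its dipole position and pre-event epochs per condition."""

    subject_id: str
    ic_id: str
    dipole_xyz: np.ndarray  # (3,) mm
    centroid_index: int
    epochs: dict[str, np.ndarray]  # condition -> (n_epochs, n_samples)
    sampling_rate: float
    window_s: tuple[float, float] = (-5.0, 0.0)


# ---------------------------------------------------------------------------
# cohort generation


def _softplus(x):
    return np.log1p(np.exp(-np.abs(x))) + np.maximum(x, 0.0)


def _suppression_factor(ability, kappa: float):
    """Rate multiplier under suppression: positive and decreasing in ability."""
    return np.exp(-_softplus(ability) * kappa)


def _suppression_factor_mean(kappa: float) -> float:
    # E over a standard-normal ability, via Gauss-Hermite quadrature
    nodes, weights = np.polynomial.hermite.hermgauss(61)
    vals = _suppression_factor(np.sqrt(2.0) * nodes, kappa)
    return float((weights * vals).sum() / np.sqrt(np.pi))


def _draw_event_train(
    rng: np.random.Generator, rate_per_min: float, duration_s: float, refractory_s: float
) -> np.ndarray:
    """Refractory Poisson train whose mean rate equals ``rate_per_min``.

    Inter-event gaps are ``refractory + Exp(lambda)`` with lambda renormalised
    so the mean gap is ``1/rate``; the first event needs no refractory wait.
    """
    if rate_per_min <= 0:
        return np.empty(0)
    rho = rate_per_min / 60.0
    if rho * refractory_s >= 1.0:
        raise ValueError(
            f"rate {rate_per_min}/min is incompatible with a {refractory_s} s refractory period"
        )
    lam = 1.0 / (1.0 / rho - refractory_s)
    times = []
    t = rng.exponential(1.0 / lam)
    while t <= duration_s:
        times.append(t)
        t += refractory_s + rng.exponential(1.0 / lam)
    return np.asarray(times)


def generate_cohort(config: CohortConfig) -> CohortTable:
    """Draw a full synthetic cohort: subjects, covariates, and event trains.

    Subjects whose event count falls below ``config.min_events`` in any
    condition are flagged ``excluded`` (they stay in the table).
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(0,)))
    z_supp = _suppression_factor_mean(config.suppression_kappa)
    subj_rows = []
    event_rows = []
    idx = 0
    for group in GROUPS:
        if group not in config.n_per_group:
            continue
        n = config.n_per_group[group]
        mean_age, sd_age, lo_age, hi_age = _AGE_MODEL[group]
        sigma_g = config.rate_dispersion[group]
        for _ in range(n):
            sid = f"S{idx:03d}"
            idx += 1
            age = float(np.clip(rng.normal(mean_age, sd_age), lo_age, hi_age))
            sex = "M" if rng.random() < _MALE_FRACTION[group] else "F"
            drug = bool(rng.random() < _DRUG_FRACTION[group])
            if group in _PUTS_MODEL:
                m, s = _PUTS_MODEL[group]
                puts = float(np.clip(rng.normal(m, s), 0.0, None))
            else:
                puts = float("nan")
            ability = float(rng.standard_normal())
            duration_s = float(rng.uniform(*config.block_duration_min)) * 60.0
            subject_mult = float(rng.lognormal(-0.5 * sigma_g**2, sigma_g))
            excluded = False
            for condition in CONDITIONS:
                base = config.event_rate[(group, condition)]
                eps = float(
                    rng.lognormal(-0.5 * config.condition_noise**2, config.condition_noise)
                )
                rate = base * subject_mult * eps
                if condition in SUPPRESSION_CONDITIONS:
                    rate *= _suppression_factor(ability, config.suppression_kappa) / z_supp
                if config.refractory_s > 0:
                    # the refractory period caps the attainable rate
                    rate = min(rate, 0.95 * 60.0 / config.refractory_s)
                times = _draw_event_train(rng, rate, duration_s, config.refractory_s)
                if times.size < config.min_events:
                    excluded = True
                for t in times:
                    event_rows.append((sid, condition, float(t), duration_s))
            subj_rows.append((sid, group, age, sex, drug, puts, ability, excluded))
    subjects = pd.DataFrame(
        subj_rows,
        columns=[
            "subject_id",
            "group",
            "age",
            "sex",
            "drug",
            "puts",
            "latent_ability",
            "excluded",
        ],
    )
    events = pd.DataFrame(
        event_rows, columns=["subject_id", "condition", "event_time_s", "block_duration_s"]
    )
    return CohortTable(subjects=subjects, events=events, config=config)


# ---------------------------------------------------------------------------
# IC-level epoch simulation

#: pre-event epoch length, seconds
EPOCH_S = 5.0
#: cosine ramp length for injected amplitude envelopes, seconds
_RAMP_S = 0.25


def _pink_noise(rng: np.random.Generator, n_epochs: int, n_samples: int, sd: float):
    white = rng.standard_normal((n_epochs, n_samples))
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n_samples)
    f[0] = f[1]
    spec *= f**-0.5
    shaped = np.fft.irfft(spec, n=n_samples, axis=-1)
    return shaped * (sd / shaped.std())


def _burst_envelope(t: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    """0..1 envelope: raised-cosine ramps of ``_RAMP_S`` inside the window."""
    t0, t1 = window
    ramp = min(_RAMP_S, (t1 - t0) / 2.0)
    env = np.zeros_like(t)
    inside = (t >= t0) & (t <= t1)
    env[inside] = 1.0
    if ramp > 0:
        up = inside & (t < t0 + ramp)
        env[up] = 0.5 * (1 - np.cos(np.pi * (t[up] - t0) / ramp))
        down = inside & (t > t1 - ramp)
        env[down] = 0.5 * (1 - np.cos(np.pi * (t1 - t[down]) / ramp))
    return env


def simulate_ic_epochs(
    subject,
    events: dict[str, EventSeries],
    config: CohortConfig,
    rng: np.random.Generator | None = None,
    ic_id: str = "ic00",
    centroid_index: int | None = None,
) -> ICEpochSet:
    """Simulate one IC's pre-event epochs and dipole position.

    ``subject`` is a row of ``CohortTable.subjects`` (or any mapping with
    ``group`` and ``latent_ability``).  Events earlier than 5 s into the
    block are dropped (the pre-event window would leave the recording); an
    empty retained-event set in any condition raises ``ValueError``.
    """
    rng = np.random.default_rng() if rng is None else rng
    group = subject["group"]
    ability = float(subject["latent_ability"])
    sid = str(subject["subject_id"])
    sfreq = config.sampling_rate
    n_samples = int(round(EPOCH_S * sfreq))
    t_epoch = -EPOCH_S + np.arange(n_samples) / sfreq

    centroids = config.centroids()
    if centroid_index is None:
        centroid_index = int(rng.integers(len(centroids)))
    role, centre = centroids[centroid_index]
    dipole = centre + rng.normal(0.0, config.centroid_sd_mm, size=3)

    active = [
        eff
        for eff in config.effect_spec
        if eff.cluster_roles is None or role in eff.cluster_roles
    ]

    epochs: dict[str, np.ndarray] = {}
    for condition, series in events.items():
        retained = series.event_times_s[series.event_times_s >= EPOCH_S]
        if retained.size == 0:
            raise ValueError(
                f"no retained events for {sid}/{condition}: all events fall "
                "within 5 s of block start"
            )
        data = _pink_noise(rng, retained.size, n_samples, config.noise_sd)
        for eff in active:
            db = eff.amplitude_db.get((group, condition), 0.0)
            if condition in SUPPRESSION_CONDITIONS:
                db = db * (1.0 + config.coupling_beta * ability)
            ratio = 10.0 ** (db / 20.0)
            env = 1.0 + (ratio - 1.0) * _burst_envelope(t_epoch, eff.window_s)
            phases = rng.uniform(0.0, 2.0 * np.pi, size=retained.size)
            carrier = np.sin(
                2.0 * np.pi * eff.carrier_hz * t_epoch[None, :] + phases[:, None]
            )
            data += config.carrier_amplitude * env[None, :] * carrier
        epochs[condition] = data
    return ICEpochSet(
        subject_id=sid,
        ic_id=ic_id,
        dipole_xyz=dipole,
        centroid_index=centroid_index,
        epochs=epochs,
        sampling_rate=sfreq,
    )


def simulate_cohort_ics(
    cohort: CohortTable,
    config: CohortConfig | None = None,
    include_excluded: bool = False,
) -> list[ICEpochSet]:
    """Simulate every subject's ICs (a seeded, deterministic sweep).

    Subjects with no retained events in some condition are skipped.
    """
    config = cohort.config if config is None else config
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(1,)))
    out: list[ICEpochSet] = []
    table = cohort.subjects if include_excluded else cohort.included()
    for _, subject in table.iterrows():
        n_ics = int(rng.integers(config.ics_per_subject[0], config.ics_per_subject[1] + 1))
        events = {c: cohort.event_series(subject.subject_id, c) for c in CONDITIONS}
        for k in range(n_ics):
            try:
                out.append(
                    simulate_ic_epochs(
                        subject, events, config, rng=rng, ic_id=f"ic{k:02d}"
                    )
                )
            except ValueError:
                break  # subject cannot contribute epochs in some condition
    return out


def simulate_summary_pairs(
    n: int, rho: float, seed: int = 0, group: str = "CTD"
) -> pd.DataFrame:
    """Per-subject (mask-mean dERSP, suppression score) pairs with a known
    population correlation.

    Both quantities load on the same unit-variance latent ability with
    independent Gaussian noise whose variance is set so that
    ``corr(summary, score) = rho`` exactly at the population level.  This is
    the calibrated fast path for studying the brain-behaviour correlation
    machinery at scale without simulating epochs.
    """
    if not (0.0 <= rho < 1.0):
        raise ValueError("rho must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    ability = rng.standard_normal(n)
    if rho == 0.0:
        summary = rng.standard_normal(n)
        score = rng.standard_normal(n)
    else:
        noise_sd = np.sqrt(1.0 / rho - 1.0)
        summary = ability + rng.normal(0.0, noise_sd, n)
        score = ability + rng.normal(0.0, noise_sd, n)
    return pd.DataFrame(
        {
            "subject_id": [f"S{i:03d}" for i in range(n)],
            "group": group,
            "delta_summary": summary,
            "suppression_score": score,
        }
    )


# ---------------------------------------------------------------------------
# fixture I/O

FIXTURE_LAYOUT_VERSION = "1"


def _config_to_json(config: CohortConfig) -> dict:
    d = dataclasses.asdict(config)
    d["event_rate"] = [[g, c, r] for (g, c), r in config.event_rate.items()]
    d["effect_spec"] = [
        {
            "band_hz": list(e.band_hz),
            "window_s": list(e.window_s),
            "amplitude_db": [[g, c, v] for (g, c), v in e.amplitude_db.items()],
            "cluster_roles": list(e.cluster_roles) if e.cluster_roles else None,
        }
        for e in config.effect_spec
    ]
    return d


def config_from_json(d: dict) -> CohortConfig:
    d = dict(d)
    d["event_rate"] = {(g, c): r for g, c, r in d["event_rate"]}
    d["effect_spec"] = [
        EffectSpec(
            band_hz=tuple(e["band_hz"]),
            window_s=tuple(e["window_s"]),
            amplitude_db={(g, c): v for g, c, v in e["amplitude_db"]},
            cluster_roles=tuple(e["cluster_roles"]) if e["cluster_roles"] else None,
        )
        for e in d["effect_spec"]
    ]
    for key in ("block_duration_min", "ics_per_subject"):
        d[key] = tuple(d[key])
    return CohortConfig(**d)


def write_fixture(
    cohort: CohortTable, ic_data: list[ICEpochSet], path: str | Path
) -> None:
    """Write a cohort and its IC epoch data to ``path`` (a directory).

    Layout: ``cohort.csv``, ``events.csv``, ``config.json`` and
    ``ic_epochs.h5`` with ``/subjects/<id>/ics/<k>/dipole_xyz`` and
    ``.../<condition>/epochs`` datasets.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    cohort.subjects.to_csv(path / "cohort.csv", index=False)
    cohort.events.to_csv(path / "events.csv", index=False)
    with open(path / "config.json", "w") as fh:
        json.dump(_config_to_json(cohort.config), fh, indent=1)
    with h5py.File(path / "ic_epochs.h5", "w") as h5:
        h5.attrs["layout_version"] = FIXTURE_LAYOUT_VERSION
        h5.attrs["sampling_rate"] = cohort.config.sampling_rate
        h5.attrs["window"] = "[-5,0] s"
        root = h5.create_group("subjects")
        for ic in ic_data:
            grp = root.require_group(f"{ic.subject_id}/ics/{ic.ic_id}")
            grp.create_dataset("dipole_xyz", data=ic.dipole_xyz)
            grp.attrs["centroid_index"] = ic.centroid_index
            for condition, data in ic.epochs.items():
                grp.create_dataset(f"{condition}/epochs", data=data)


def read_fixture(path: str | Path) -> tuple[CohortTable, list[ICEpochSet]]:
    """Read back a fixture written by :func:`write_fixture` (lossless)."""
    path = Path(path)
    for name in ("cohort.csv", "events.csv", "config.json", "ic_epochs.h5"):
        if not (path / name).exists():
            raise FileNotFoundError(f"fixture file missing: {path / name}")
    with open(path / "config.json") as fh:
        config = config_from_json(json.load(fh))
    subjects = pd.read_csv(
        path / "cohort.csv",
        dtype={"subject_id": str, "group": str, "sex": str},
    )
    if subjects.empty:
        subjects = subjects.reindex(
            columns=[
                "subject_id",
                "group",
                "age",
                "sex",
                "drug",
                "puts",
                "latent_ability",
                "excluded",
            ]
        )
    events = pd.read_csv(path / "events.csv", dtype={"subject_id": str, "condition": str})
    if events.empty:
        events = events.reindex(
            columns=["subject_id", "condition", "event_time_s", "block_duration_s"]
        )
    ic_data: list[ICEpochSet] = []
    with h5py.File(path / "ic_epochs.h5", "r") as h5:
        version = h5.attrs.get("layout_version")
        if version != FIXTURE_LAYOUT_VERSION:
            raise ValueError(
                f"fixture layout version {version!r} != {FIXTURE_LAYOUT_VERSION!r}"
            )
        sfreq = float(h5.attrs["sampling_rate"])
        subjects_grp = h5.get("subjects", {})
        for sid in subjects_grp:
            for ic_id in subjects_grp[sid]["ics"]:
                grp = subjects_grp[sid]["ics"][ic_id]
                epochs = {
                    cond: grp[cond]["epochs"][()]
                    for cond in grp
                    if cond != "dipole_xyz"
                }
                ic_data.append(
                    ICEpochSet(
                        subject_id=sid,
                        ic_id=ic_id,
                        dipole_xyz=grp["dipole_xyz"][()],
                        centroid_index=int(grp.attrs["centroid_index"]),
                        epochs=epochs,
                        sampling_rate=sfreq,
                    )
                )
    return CohortTable(subjects=subjects, events=events, config=config), ic_data
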