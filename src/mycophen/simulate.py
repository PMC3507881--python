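"""Synthetic mushroom-census generator.

Emulates the statistical structure of a ~30-year monthly fruiting census in a
warm-temperate Japanese oak forest: sinusoidal daily temperature peaking in
August (annual mean ~16 degC, January mean ~4.6, August mean ~28.8), seasonal
Gamma-distributed daily rainfall calibrated to ~1480 mm per year, monthly
surveys with independent missingness (347 scheduled months of which ~274 are
realized), guild-structured species pools (271 ECM / 137 litter-decomposer /
236 wood-decomposer species), logit-scale fruiting responses to the
standardized climate covariates, and imperfect per-survey detection.

The forward model is exactly the inference model: for each realized survey
``i`` and group ``j``, the latent fruiting count is
``X[i,j] ~ Binomial(N_j, expit(alpha_j + x_i . beta_j))`` on the covariates
built the same way the analysis builds them, and the observed count is
``D[i,j] ~ Binomial(X[i,j], d)``.  Detected counts are materialized as
concrete species identities so the generator emits the exact three-table
format the readers consume; the hidden truth (latent counts, true
coefficients, detection values) is returned separately for recovery tests.

All randomness flows from one root seed through named substreams (climate,
missingness, presence, detection, identity, genus effects) so components can
be varied independently.
"""

from __future__ import annotations

import calendar
import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from . import io as _io
from .io import (CovariateTable, DetectionMatrix, Guild, SpeciesRecord,
                 SurveyEvent)

__all__ = [
    "GroupSpec",
    "DetectionSpec",
    "ClimateSpec",
    "SurveySpec",
    "SimulationTruth",
    "SyntheticDataset",
    "default_truth",
    "default_genus_truth",
    "generate_climate",
    "generate_dataset",
]

# substream indices off the root seed
_CLIMATE, _MISSING, _PRESENCE, _DETECTION, _IDENTITY, _GENUS = range(6)

_COV = _io.COVARIATE_NAMES


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, stream]))


@dataclass(frozen=True)
class GroupSpec:
    """One simulated species group: its pool size and true fruiting
    response ``logit p = alpha + beta . x`` on standardized covariates."""

    label: str
    guild: Guild
    n_species: int
    alpha: float
    beta: tuple[float, float, float, float]  # over (T, MR, WR, Y)

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")
        if len(self.beta) != len(_COV):
            raise ValueError(f"beta must have {len(_COV)} entries")


@dataclass(frozen=True)
class DetectionSpec:
    """True detection process: a constant probability shared by all surveys,
    or per-survey values drawn from a Beta distribution."""

    structure: str = "constant"           # "constant" | "per_survey"
    value: float = 0.8
    concentration: float = 30.0           # Beta concentration for per_survey

    def __post_init__(self) -> None:
        if self.structure not in ("constant", "per_survey"):
            raise ValueError("structure must be 'constant' or 'per_survey'")
        if not 0 < self.value <= 1:
            raise ValueError("detection value must be in (0, 1]")
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")


@dataclass(frozen=True)
class ClimateSpec:
    """Seasonal daily climate.

    Temperature: ``mean + amplitude * cos(2 pi (doy - peak_doy)/365.25)``
    plus Normal noise.  Defaults give an annual mean of 15.96 degC ranging
    from ~4 degC (January) to ~28 degC (mid-August).  Rainfall: daily totals
    are Gamma with a seasonally varying mean calibrated so the long-run
    annual total is ``rain_annual_mm`` (default 1480 mm), peaking in early
    summer; a small shape parameter yields realistic dry-day skew.
    """

    temp_mean: float = 15.96
    temp_amplitude: float = 12.1
    temp_noise_sd: float = 1.5
    temp_peak_doy: int = 227              # mid-August
    rain_annual_mm: float = 1480.0
    rain_seasonality: float = 0.6         # relative amplitude of daily mean
    rain_shape: float = 0.35
    rain_peak_doy: int = 180              # late-June rainy season

    def __post_init__(self) -> None:
        if self.temp_noise_sd < 0 or self.rain_shape <= 0:
            raise ValueError("variance parameters must be positive")
        if not 0 <= self.rain_seasonality < 1:
            raise ValueError("rain_seasonality must be in [0, 1)")


@dataclass(frozen=True)
class SurveySpec:
    """Monthly survey schedule with independent missingness."""

    start: _dt.date = _dt.date(1982, 5, 15)
    n_months: int = 347
    missing_prob: float = 0.21
    day_of_month: int = 15

    def __post_init__(self) -> None:
        if not 0 <= self.missing_prob < 1:
            raise ValueError("missing_prob must be in [0, 1)")
        if self.n_months < 1:
            raise ValueError("n_months must be >= 1")


@dataclass(frozen=True)
class SimulationTruth:
    """Full specification of one simulated census."""

    groups: tuple[GroupSpec, ...]
    detection: DetectionSpec = DetectionSpec()
    climate: ClimateSpec = ClimateSpec()
    survey: SurveySpec = SurveySpec()
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("need at least one group")


def default_truth(seed: int = 0, n_months: int = 347,
                  missing_prob: float = 0.21) -> SimulationTruth:
    """Guild-level defaults at census scale.

    Pool sizes follow the observed guild richness (271/137/236).  The
    ECM-like group responds strongly and positively to temperature and
    monthly rainfall with a slight negative weekly-rain effect; the
    litter-like group is moderately seasonal; the wood-like group is weakly
    seasonal with a time-dependent increase.
    """
    groups = (
        GroupSpec("ECM", Guild.ECM, 271, -2.0, (0.8, 0.5, -0.1, 0.1)),
        GroupSpec("LITTER", Guild.LITTER, 137, -2.2, (0.3, 0.6, -0.05, 0.0)),
        GroupSpec("WOOD", Guild.WOOD, 236, -2.0, (-0.2, 0.3, 0.1, 0.4)),
    )
    return SimulationTruth(groups=groups, seed=seed,
                           survey=SurveySpec(n_months=n_months,
                                             missing_prob=missing_prob))


#: Guild-level templates (alpha, beta, per-coefficient jitter sd) used to
#: derive heterogeneous genus-level effects: ECM genera share similar
#: responses, litter genera vary moderately, wood genera vary strongly
#: (sign-heterogeneous).
_GENUS_TEMPLATES = {
    Guild.ECM: (-2.0, (0.8, 0.5, -0.1, 0.1), 0.1),
    Guild.LITTER: (-2.2, (0.3, 0.6, -0.05, 0.0), 0.3),
    Guild.WOOD: (-2.0, (0.0, 0.2, 0.0, 0.2), 0.5),
}

_GUILD_POOL = {Guild.ECM: 271, Guild.LITTER: 137, Guild.WOOD: 236}


def default_genus_truth(seed: int = 0, n_months: int = 347,
                        missing_prob: float = 0.21) -> SimulationTruth:
    """Genus-level defaults: the 21 frequent genera, seven per guild, with
    per-genus effects jittered around their guild template (deterministic
    given the seed via the genus-effects substream)."""
    rng = _rng(seed, _GENUS)
    groups = []
    by_guild: dict[Guild, list[str]] = {}
    for genus, guild in _io.DEFAULT_GENERA.items():
        by_guild.setdefault(guild, []).append(genus)
    for guild, genera in by_guild.items():
        alpha0, beta0, jitter = _GENUS_TEMPLATES[guild]
        pool = _GUILD_POOL[guild]
        base, extra = divmod(pool, len(genera))
        for i, genus in enumerate(genera):
            beta = tuple(np.asarray(beta0) + rng.normal(0.0, jitter, len(_COV)))
            groups.append(GroupSpec(genus, guild, base + (1 if i < extra else 0),
                                    alpha0 + rng.normal(0.0, 0.2), beta))
    return SimulationTruth(groups=tuple(groups), seed=seed,
                           survey=SurveySpec(n_months=n_months,
                                             missing_prob=missing_prob))


def census_from_margins(species_per_guild: dict[Guild, int],
                        records_per_guild: dict[Guild, int],
                        start: _dt.date = _dt.date(1982, 5, 15),
                        ) -> tuple[list[SpeciesRecord], list[SurveyEvent]]:
    """Construct a census realizing exact per-guild margins.

    Builds the smallest monthly survey series in which each guild has exactly
    the requested number of distinct observed species and total detection
    records (records spread as evenly as possible across the guild's
    species).  Useful for checks that only depend on the count margins.
    """
    species: list[SpeciesRecord] = []
    repeats: dict[str, int] = {}
    for guild, n_sp in species_per_guild.items():
        n_rec = records_per_guild[guild]
        if n_rec < n_sp:
            raise ValueError(f"{guild}: fewer records than species")
        base, extra = divmod(n_rec, n_sp)
        for k in range(n_sp):
            sid = f"{guild.value.lower()}_{k:04d}"
            species.append(SpeciesRecord(sid, guild.value.title(),
                                         f"{guild.value.title()}aceae", guild))
            repeats[sid] = base + (1 if k < extra else 0)
    n_surveys = max(repeats.values())
    surveys = []
    for m in range(n_surveys):
        hit = frozenset(sid for sid, r in repeats.items() if m < r)
        surveys.append(SurveyEvent(m + 1, _add_months(start, m), hit))
    return species, surveys


# ---------------------------------------------------------------------------
# climate

def _add_months(d: _dt.date, months: int) -> _dt.date:
    y, m = divmod(d.month - 1 + months, 12)
    year, month = d.year + y, m + 1
    day = min(d.day, calendar.monthrange(year, month)[1])
    return _dt.date(year, month, day)


def _survey_span(spec: SurveySpec) -> tuple[_dt.date, _dt.date]:
    first = spec.start
    last = _add_months(first, spec.n_months - 1)
    return first, last


def generate_climate(truth: SimulationTruth) -> pd.DataFrame:
    """Daily climate covering the survey span plus the longest covariate
    window (40 days of lead-in)."""
    spec = truth.climate
    first, last = _survey_span(truth.survey)
    dates = pd.date_range(pd.Timestamp(first) - pd.Timedelta(days=40),
                          pd.Timestamp(last), freq="D")
    doy = dates.dayofyear.to_numpy(dtype=float)
    rng = _rng(truth.seed, _CLIMATE)

    phase = 2.0 * np.pi * (doy - spec.temp_peak_doy) / 365.25
    temp = spec.temp_mean + spec.temp_amplitude * np.cos(phase)
    if spec.temp_noise_sd > 0:
        temp = temp + rng.normal(0.0, spec.temp_noise_sd, len(dates))

    daily_mean = spec.rain_annual_mm / 365.25
    rain_phase = 2.0 * np.pi * (doy - spec.rain_peak_doy) / 365.25
    mu = daily_mean * (1.0 + spec.rain_seasonality * np.cos(rain_phase))
    rain = rng.gamma(spec.rain_shape, mu / spec.rain_shape)

    return pd.DataFrame({"date": dates, "temp_mean_c": temp,
                         "rain_mm": rain}).set_index("date")


# ---------------------------------------------------------------------------
# dataset

@dataclass
class SyntheticDataset:
    """A materialized census plus its hidden truth.

    ``species``/``surveys``/``climate`` are exactly what the readers consume;
    ``matrix``/``covariates`` are the generator's own data objects (``matrix``
    carries the generative pool sizes as N); ``latent_x``, ``d_values`` and
    ``truth`` are the hidden state for recovery tests and are never consumed
    by the analysis pipeline.
    """

    truth: SimulationTruth
    species: list[SpeciesRecord]
    surveys: list[SurveyEvent]
    climate: pd.DataFrame
    matrix: DetectionMatrix
    covariates: CovariateTable
    latent_x: np.ndarray
    d_values: np.ndarray
    true_alpha: np.ndarray = field(init=False)
    true_beta: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.true_alpha = np.array([g.alpha for g in self.truth.groups])
        self.true_beta = np.array([g.beta for g in self.truth.groups])

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Emit the three input tables plus a truth manifest (JSON; test
        harness only — the pipeline never reads it)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "species": outdir / "species.csv",
            "detections": outdir / "detections.csv",
            "climate": outdir / "climate.csv",
            "truth": outdir / "truth.json",
        }
        _io.write_species_table(self.species, paths["species"])
        _io.write_detections(self.surveys, paths["detections"])
        self.climate.reset_index().assign(
            date=lambda f: f["date"].dt.date).to_csv(paths["climate"],
                                                     index=False)
        manifest = {
            "seed": self.truth.seed,
            "groups": [{"label": g.label, "guild": g.guild.value,
                        "n_species": g.n_species, "alpha": g.alpha,
                        "beta": list(g.beta)} for g in self.truth.groups],
            "detection": {"structure": self.truth.detection.structure,
                          "values": np.atleast_1d(self.d_values).tolist()},
            "n_surveys": len(self.surveys),
        }
        paths["truth"].write_text(json.dumps(manifest, indent=2) + "\n")
        return paths


def generate_dataset(truth: SimulationTruth,
                     shuffle_identities: bool = False) -> SyntheticDataset:
    """Simulate one census from the generative presence/detection model.

    Detected counts are materialized as the lowest-indexed species ids of
    each group (the counts, not the identities, carry the model's
    information); ``shuffle_identities=True`` instead samples which species
    are reported, for I/O stress tests.
    """
    climate = generate_climate(truth)
    spec = truth.survey

    miss_rng = _rng(truth.seed, _MISSING)
    scheduled = [_add_months(spec.start, m) for m in range(spec.n_months)]
    keep = miss_rng.random(spec.n_months) >= spec.missing_prob
    dates = [d for d, k in zip(scheduled, keep) if k]
    ids = [m + 1 for m, k in enumerate(keep) if k]
    if not dates:
        raise RuntimeError("all surveys missing; lower missing_prob")

    blank = [SurveyEvent(i, d, frozenset()) for i, d in zip(ids, dates)]
    covariates = _io.build_covariates(blank, climate)

    alpha = np.array([g.alpha for g in truth.groups])
    beta = np.array([g.beta for g in truth.groups])
    n_pool = np.array([g.n_species for g in truth.groups])
    p = expit(alpha[None, :] + covariates.x @ beta.T)   # surveys x groups

    presence_rng = _rng(truth.seed, _PRESENCE)
    X = presence_rng.binomial(n_pool[None, :], p)

    det_rng = _rng(truth.seed, _DETECTION)
    det = truth.detection
    if det.structure == "constant":
        d_values = np.float64(det.value)
        d_mat = np.broadcast_to(d_values, X.shape)
    else:
        a = det.value * det.concentration
        b = (1.0 - det.value) * det.concentration
        d_values = det_rng.beta(a, b, size=len(dates))
        d_mat = np.broadcast_to(d_values[:, None], X.shape)
    D = det_rng.binomial(X, d_mat)

    species: list[SpeciesRecord] = []
    pool_ids: list[list[str]] = []
    for g in truth.groups:
        ids_g = [f"{g.label.lower()}_s{i:04d}" for i in range(g.n_species)]
        pool_ids.append(ids_g)
        genus = g.label if g.label in _io.DEFAULT_GENERA else g.guild.value.title()
        for sid in ids_g:
            species.append(SpeciesRecord(species_id=sid, genus=genus,
                                         family=f"{genus}aceae",
                                         guild=g.guild, hypogeous=False))

    id_rng = _rng(truth.seed, _IDENTITY)
    surveys: list[SurveyEvent] = []
    for i, (sid, date) in enumerate(zip(ids, dates)):
        detected: list[str] = []
        for j, g in enumerate(truth.groups):
            k = int(D[i, j])
            if shuffle_identities:
                chosen = id_rng.choice(g.n_species, size=k, replace=False)
                detected.extend(pool_ids[j][c] for c in chosen)
            else:
                detected.extend(pool_ids[j][:k])
        surveys.append(SurveyEvent(sid, date, frozenset(detected)))

    matrix = DetectionMatrix(
        D=D, N=n_pool, groups=[g.label for g in truth.groups],
        dates=list(dates), survey_ids=ids,
        group_guilds={g.label: g.guild for g in truth.groups},
    )
    return SyntheticDataset(truth=truth, species=species, surveys=surveys,
                            climate=climate, matrix=matrix,
                            covariates=covariates, latent_x=X,
                            d_values=np.asarray(d_values))
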