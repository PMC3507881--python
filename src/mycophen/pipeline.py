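"""End-to-end orchestration: read (or simulate) a census, fit the
presence/detection model, run the seasonal statistics, and write tidy tables
plus a reproducible run manifest.

Every stage logs one line with its input/output row counts.  The manifest
echoes the full configuration and seed, so a run can be reproduced
bit-for-bit from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as _io
from . import phenology as _ph
from . import simulate as _sim
from .io import CovariateWindows, Guild
from .zib import ZIBConfig, ZIBModel

__all__ = ["RunConfig", "run_pipeline", "report_group_counts",
           "default_config_yaml"]

log = logging.getLogger("mycophen")

_GUILD_ORDER = [Guild.ECM, Guild.LITTER, Guild.WOOD, Guild.OTHER]


@dataclass
class RunConfig:
    """Validated pipeline configuration.

    Exactly one of ``inputs`` (paths to the three tables) or ``simulate``
    (an inline :class:`~mycophen.simulate.SimulationTruth`) must be set.
    """

    inputs: dict[str, str] | None = None
    simulate: _sim.SimulationTruth | None = None
    exclude_hypogeous: bool = True
    windows: CovariateWindows = CovariateWindows()
    zib: ZIBConfig = field(default_factory=ZIBConfig.desk)
    fit_enabled: bool = True
    fit_genus_level: bool = False
    alpha: float = 0.05
    kendall_tie_correction: bool = True
    kendall_n_perm: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.inputs is None and self.simulate is None:
            raise ValueError("config needs either input paths or a "
                             "simulation spec")
        if self.inputs is not None and self.simulate is not None:
            raise ValueError("give input paths or a simulation spec, not both")
        if self.inputs is not None:
            missing = {"species", "detections", "climate"} - set(self.inputs)
            if missing:
                raise ValueError(f"inputs missing paths for {sorted(missing)}")

    # -- construction from config files -------------------------------------

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kw: dict = {}
        if "inputs" in raw and raw["inputs"]:
            kw["inputs"] = dict(raw["inputs"])
        if "simulate" in raw and raw["simulate"]:
            kw["simulate"] = _truth_from_dict(raw["simulate"])
        if "windows" in raw:
            kw["windows"] = CovariateWindows(**raw["windows"])
        if "zib" in raw:
            kw["zib"] = ZIBConfig(**raw["zib"])
        fit = raw.get("fit", {})
        if "enabled" in fit:
            kw["fit_enabled"] = bool(fit["enabled"])
        if "genus_level" in fit:
            kw["fit_genus_level"] = bool(fit["genus_level"])
        for key in ("exclude_hypogeous", "alpha", "log_level"):
            if key in raw:
                kw[key] = raw[key]
        kendall = raw.get("kendall", {})
        if "tie_correction" in kendall:
            kw["kendall_tie_correction"] = bool(kendall["tie_correction"])
        if "n_perm" in kendall:
            kw["kendall_n_perm"] = int(kendall["n_perm"])
        return cls(**kw)

    def to_dict(self) -> dict:
        out: dict = {
            "exclude_hypogeous": self.exclude_hypogeous,
            "windows": dataclasses.asdict(self.windows),
            "zib": {k: (v if not isinstance(v, np.ndarray) else v.tolist())
                    for k, v in dataclasses.asdict(self.zib).items()},
            "fit": {"enabled": self.fit_enabled,
                    "genus_level": self.fit_genus_level},
            "alpha": self.alpha,
            "kendall": {"tie_correction": self.kendall_tie_correction,
                        "n_perm": self.kendall_n_perm},
            "log_level": self.log_level,
        }
        if self.inputs is not None:
            out["inputs"] = dict(self.inputs)
        if self.simulate is not None:
            t = self.simulate
            out["simulate"] = {
                "seed": t.seed,
                "groups": [{"label": g.label, "guild": g.guild.value,
                            "n_species": g.n_species, "alpha": g.alpha,
                            "beta": list(g.beta)} for g in t.groups],
                "detection": dataclasses.asdict(t.detection),
                "climate": dataclasses.asdict(t.climate),
                "survey": {"start": t.survey.start.isoformat(),
                           "n_months": t.survey.n_months,
                           "missing_prob": t.survey.missing_prob,
                           "day_of_month": t.survey.day_of_month},
            }
        return out


def _truth_from_dict(raw: dict) -> _sim.SimulationTruth:
    seed = int(raw.get("seed", 0))
    n_months = int(raw.get("n_months", 347))
    missing = float(raw.get("missing_prob", 0.21))
    groups_raw = raw.get("groups", "default_guilds")
    if groups_raw == "default_guilds":
        return _sim.default_truth(seed=seed, n_months=n_months,
                                  missing_prob=missing)
    if groups_raw == "default_genera":
        return _sim.default_genus_truth(seed=seed, n_months=n_months,
                                        missing_prob=missing)
    groups = tuple(
        _sim.GroupSpec(g["label"], Guild(g["guild"]), int(g["n_species"]),
                       float(g["alpha"]), tuple(g["beta"]))
        for g in groups_raw)
    kw: dict = {}
    if "detection" in raw:
        kw["detection"] = _sim.DetectionSpec(**raw["detection"])
    if "climate" in raw:
        kw["climate"] = _sim.ClimateSpec(**raw["climate"])
    survey_kw = dict(n_months=n_months, missing_prob=missing)
    if "survey" in raw:
        sv = dict(raw["survey"])
        if "start" in sv:
            sv["start"] = pd.Timestamp(sv["start"]).date()
        survey_kw.update(sv)
    return _sim.SimulationTruth(groups=groups, seed=seed,
                                survey=_sim.SurveySpec(**survey_kw), **kw)


def default_config_yaml() -> str:
    """The default configuration, printable via the CLI's --show-config."""
    cfg = RunConfig(simulate=_sim.default_truth())
    return yaml.safe_dump(cfg.to_dict(), sort_keys=False)


# ---------------------------------------------------------------------------

def report_group_counts(species, surveys) -> pd.DataFrame:
    """Distinct observed species and total records per guild, with totals.

    A record is one (survey, species) detection pair; a species counts
    toward its guild if it was detected in at least one survey.
    """
    by_id = {r.species_id: r for r in species}
    seen: dict[Guild, set[str]] = {g: set() for g in _GUILD_ORDER}
    records: dict[Guild, int] = {g: 0 for g in _GUILD_ORDER}
    for ev in surveys:
        for sp in ev.detections:
            guild = by_id[sp].guild
            seen[guild].add(sp)
            records[guild] += 1
    rows = [{"guild": g.value, "n_species": len(seen[g]),
             "n_records": records[g]} for g in _GUILD_ORDER]
    total = {"guild": "TOTAL",
             "n_species": sum(r["n_species"] for r in rows),
             "n_records": sum(r["n_records"] for r in rows)}
    return pd.DataFrame(rows + [total])


def _stage(name: str, **counts) -> None:
    detail = ", ".join(f"{k}={v}" for k, v in counts.items())
    log.info("%s: %s", name, detail)


def run_pipeline(config: RunConfig, outdir: str | Path,
                 seed: int | None = None) -> dict[str, Path]:
    """Execute read/simulate -> model fit -> seasonal statistics -> tables.

    ``seed`` overrides both the simulation seed and the sampler seed, so one
    integer reproduces the whole run.  Returns the paths written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if seed is not None:
        config = replace(config, zib=replace(config.zib, seed=seed))
        if config.simulate is not None:
            config = replace(config,
                             simulate=replace(config.simulate, seed=seed))

    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(config.log_level)
    paths: dict[str, Path] = {"log": outdir / "run.log"}
    try:
        return _run(config, outdir, paths)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run(config: RunConfig, outdir: Path, paths: dict[str, Path]) -> dict[str, Path]:
    # -- stage: load or simulate
    if config.simulate is not None:
        data = _sim.generate_dataset(config.simulate)
        species, surveys, climate = data.species, data.surveys, data.climate
        _stage("simulate", surveys=len(surveys), species=len(species))
    else:
        species = _io.read_species_table(config.inputs["species"])
        surveys = _io.read_detections(config.inputs["detections"])
        climate = _io.read_climate(config.inputs["climate"])
        _stage("read", surveys=len(surveys), species=len(species),
               climate_days=len(climate))

    # -- stage: counts report (before any filtering)
    counts = report_group_counts(species, surveys)
    counts.to_csv(outdir / "counts.csv", index=False)
    paths["counts"] = outdir / "counts.csv"
    _stage("counts", guilds=len(counts) - 1)

    # -- stage: filter + data objects
    kept = _io.filter_species(species, config.exclude_hypogeous)
    matrix = _io.build_detection_matrix(surveys, kept, grouping="by_guild")
    covariates = _io.build_covariates(surveys, climate,
                                      windows=config.windows)
    matrix.to_csv(outdir / "detection_matrix.csv")
    covariates.to_csv(outdir / "covariates.csv")
    covariates.write_meta(outdir / "covariates_meta.json")
    paths.update(detection_matrix=outdir / "detection_matrix.csv",
                 covariates=outdir / "covariates.csv",
                 covariates_meta=outdir / "covariates_meta.json")
    _stage("build", surveys=matrix.n_surveys, groups=len(matrix.groups),
           excluded_species=len(species) - len(kept))

    # -- stage: monthly summaries, all-pairs comparisons, letters
    monthly_rows, pairwise_frames = [], []
    for g in matrix.groups:
        ms = _ph.monthly_samples(matrix, g)
        comp = _ph.steel_dwass(ms, alpha=config.alpha)
        letters = comp.letters()
        for m in _ph.MONTHS:
            v = ms.samples[m]
            monthly_rows.append({
                "group": g, "month": m, "n": len(v),
                "mean": v.mean() if len(v) else np.nan,
                "se": (v.std(ddof=1) / np.sqrt(len(v))
                       if len(v) > 1 else np.nan),
                "letters": letters.get(m, ""),
            })
        pw = comp.table.copy()
        pw.insert(0, "group", g)
        pairwise_frames.append(pw)
    pd.DataFrame(monthly_rows).to_csv(outdir / "monthly_summary.csv",
                                      index=False)
    pd.concat(pairwise_frames).to_csv(outdir / "pairwise.csv", index=False)
    paths.update(monthly_summary=outdir / "monthly_summary.csv",
                 pairwise=outdir / "pairwise.csv")
    _stage("seasonal", groups=len(matrix.groups))

    # -- stage: genus-level concordance + relative richness
    genus_matrix = _io.build_detection_matrix(
        surveys, kept, grouping="by_genus_within_guild")
    present = [g for g, n in zip(genus_matrix.groups, genus_matrix.N) if n > 0]
    conc_rows, rich_rows = [], []
    for guild in (Guild.ECM, Guild.LITTER, Guild.WOOD):
        genera = [g for g in present
                  if genus_matrix.group_guilds[g] == guild]
        if len(genera) >= 2:
            ranks = _ph.monthly_rank_matrix(genus_matrix, genera)
            res = _ph.kendall_w(ranks,
                                tie_correction=config.kendall_tie_correction,
                                n_perm=config.kendall_n_perm,
                                seed=config.zib.seed)
            conc_rows.append({"guild": guild.value, "W": res.W,
                              "m_judges": res.m_judges,
                              "n_objects": res.n_objects,
                              "chi2": res.chi2, "df": res.df,
                              "p_chi2": res.p_chi2, "p_perm": res.p_perm})
        for g in genera:
            prof = _ph.relative_richness(genus_matrix, g)
            rich_rows.append({"guild": guild.value, "genus": g,
                              **{f"m{m:02d}": prof[m - 1]
                                 for m in _ph.MONTHS}})
    pd.DataFrame(conc_rows).to_csv(outdir / "concordance.csv", index=False)
    pd.DataFrame(rich_rows).to_csv(outdir / "relative_richness.csv",
                                   index=False)
    paths.update(concordance=outdir / "concordance.csv",
                 relative_richness=outdir / "relative_richness.csv")
    _stage("concordance", guilds=len(conc_rows), genera=len(rich_rows))

    # -- stage: presence/detection model fit
    rhat_report: dict[str, float] = {}
    if config.fit_enabled:
        res = ZIBModel(matrix, covariates).fit(config.zib)
        res.save(outdir / "posterior_draws.csv", outdir / "zib_summary.csv")
        paths.update(posterior_draws=outdir / "posterior_draws.csv",
                     zib_summary=outdir / "zib_summary.csv")
        rhat_report["guild_max_rhat"] = res.max_rhat
        _stage("fit", groups=len(matrix.groups),
               retained=config.zib.n_retained, max_rhat=round(res.max_rhat, 4))
        if config.fit_genus_level:
            gres = ZIBModel(genus_matrix, covariates).fit(config.zib)
            gres.save(outdir / "posterior_draws_genus.csv",
                      outdir / "zib_summary_genus.csv")
            paths.update(
                posterior_draws_genus=outdir / "posterior_draws_genus.csv",
                zib_summary_genus=outdir / "zib_summary_genus.csv")
            rhat_report["genus_max_rhat"] = gres.max_rhat
            _stage("fit_genus", groups=len(genus_matrix.groups),
                   max_rhat=round(gres.max_rhat, 4))

    # -- stage: manifest
    cfg_dict = config.to_dict()
    run_id = hashlib.sha256(
        json.dumps(cfg_dict, sort_keys=True).encode()).hexdigest()[:12]
    manifest = {
        "run_id": run_id,
        "seed": config.zib.seed,
        "package": "mycophen 0.1.0",
        "config": cfg_dict,
        "rhat": rhat_report,
        "outputs": {k: p.name for k, p in paths.items()},
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    paths["manifest"] = outdir / "manifest.json"
    _stage("manifest", run_id=run_id)
    return paths
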