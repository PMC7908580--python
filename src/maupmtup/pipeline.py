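"""End-to-end orchestration: simulate -> zone -> prepare -> fit -> summarize.

A run is driven by a single :class:`RunConfig` and a master seed.  Every
stochastic step derives its own seed deterministically from the master seed
and the preparation descriptor, so re-running a config reproduces identical
results regardless of execution order, and a crashed run resumes from its
manifest checkpoints.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .bym import BYMConfig, BYMModel, zone_adjacency
from .lattice import gen_lattice
from .prep import aggregate_by_zonation, map_grid_to_areas, unit_window_rainfall, winter_exposure
from .rainfall import gen_rainfall
from .simulate import SimulationTruth, simulate_events, simulate_icar
from .summary import build_grid, summarize_arrangement
from .windows import PreparationKey, enumerate_preparations, window_instances
from .zonation import build_zonation_set

log = logging.getLogger(__name__)

_SEED_LATTICE, _SEED_RAIN, _SEED_ZONES, _SEED_EVENTS, _SEED_FIT = range(5)


def _child_seed(master: int, *key: int) -> int:
    ss = np.random.SeedSequence(entropy=master, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] % (2**31))


def _shift_months(d: datetime.date, months: int) -> datetime.date:
    m = d.year * 12 + (d.month - 1) + months
    return datetime.date(m // 12, m % 12 + 1, 1)


@dataclass
class RunConfig:
    """Full configuration of a pipeline run (defaults mirror the study design)."""

    # lattice
    n_rows: int = 30
    n_cols: int = 30
    grid_factor: int = 3
    pop_range: tuple[int, int] = (100, 320)
    # rainfall
    seasonal_means: tuple[float, float] = (0.43, 1.50)
    noise_sd: float = 0.5
    month_anomaly_sd: float = 0.25
    rain_lead_months: int = 30
    # ground truth of the simulated events
    alpha: float = 0.0
    beta: float = 0.0
    sigma_u2: float = 0.05
    sigma_v2: float = 0.05
    exposure: str = "winter"  # "winter" | "arrangement" | "none"
    base_rate: float = 0.02
    # study period
    study_start: datetime.date = datetime.date(2002, 1, 1)
    study_end: datetime.date = datetime.date(2017, 6, 30)
    # temporal factorial
    endpoints: tuple[int, ...] = (2, 4, 6, 8, 10, 12)
    rain_lengths: tuple[int, ...] = (3, 6)
    lags: tuple[int, ...] = (0, 6, 12, 18, 24)
    # zonations
    zonation_targets: tuple[int, ...] = (500, 1000, 2500, 5000, 7500)
    zonation_replicates: int = 5
    genders: tuple[str, ...] = ("female", "male")
    bym: BYMConfig = field(default_factory=BYMConfig)
    out_dir: str = "out"
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.study_start, str):
            self.study_start = datetime.date.fromisoformat(self.study_start)
        if isinstance(self.study_end, str):
            self.study_end = datetime.date.fromisoformat(self.study_end)
        if isinstance(self.bym, dict):
            self.bym = BYMConfig(**self.bym)
        if self.exposure not in ("winter", "arrangement", "none"):
            raise ValueError("exposure must be 'winter', 'arrangement' or 'none'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()})

    @classmethod
    def smoke(cls, seed: int = 0, out_dir: str = "out") -> "RunConfig":
        """Reduced configuration for quick end-to-end checks."""
        return cls(
            n_rows=10, n_cols=10, grid_factor=2, pop_range=(100, 320),
            endpoints=(2, 8), rain_lengths=(3,), lags=(0, 6),
            zonation_targets=(2500,), zonation_replicates=1,
            genders=("female",),
            bym=BYMConfig(chains=1, iterations=600, burn_in=300, thinning=1),
            out_dir=out_dir, seed=seed,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["study_start"] = self.study_start.isoformat()
        d["study_end"] = self.study_end.isoformat()
        return d


def _digest(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every preparation of the config; return (and write) the manifest.

    The manifest records per-preparation seeds, rate ratios and credible
    intervals; it is checkpointed after every fit, and an existing manifest
    with the same config digest is resumed rather than recomputed.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    cfg_dict = cfg.to_dict()
    cfg_digest = hashlib.sha256(json.dumps(cfg_dict, sort_keys=True).encode()).hexdigest()[:16]

    manifest: dict = {"config": cfg_dict, "config_digest": cfg_digest, "entries": {}}
    if manifest_path.exists():
        prev = json.loads(manifest_path.read_text())
        if prev.get("config_digest") == cfg_digest:
            manifest = prev
            log.info("resuming run: %d entries already present", len(manifest["entries"]))

    lattice = gen_lattice(
        cfg.n_rows, cfg.n_cols, cfg.grid_factor, cfg.pop_range,
        seed=_child_seed(cfg.seed, _SEED_LATTICE),
    )
    rain_start = _shift_months(cfg.study_start.replace(day=1), -cfg.rain_lead_months)
    field_ = gen_rainfall(
        rain_start, cfg.study_end, lattice.cell_ids,
        seasonal_means=cfg.seasonal_means, noise_sd=cfg.noise_sd,
        month_anomaly_sd=cfg.month_anomaly_sd,
        seed=_child_seed(cfg.seed, _SEED_RAIN),
    )
    unit_daily = map_grid_to_areas(field_, lattice)

    zonations = build_zonation_set(
        lattice, targets=cfg.zonation_targets, replicates=cfg.zonation_replicates,
        seed=_child_seed(cfg.seed, _SEED_ZONES),
    )
    zmap = {z.name: z for z in zonations}
    zadj = {name: zone_adjacency(z, lattice) for name, z in zmap.items()}

    manifest["digests"] = {
        "census_pops": _digest(lattice.census_pops),
        "rainfall": _digest(field_.values),
        "zonations": _digest(np.concatenate([z.labels for z in zonations])),
    }

    keys = enumerate_preparations(
        cfg.endpoints, cfg.rain_lengths, cfg.lags, list(zmap), cfg.genders
    )

    # simulate unit-level events once per (endpoint, gender) -- or per
    # arrangement when the truth exposure is the arrangement's own covariate
    sims: dict = {}

    def get_sim(key: PreparationKey, windows):
        ei = cfg.endpoints.index(key.endpoint_month)
        gi = cfg.genders.index(key.gender)
        truth = SimulationTruth(cfg.alpha, cfg.beta, cfg.sigma_u2, cfg.sigma_v2)
        if cfg.exposure == "arrangement":
            sk = (key.endpoint_month, key.rain_length_months, key.lag_months, key.gender)
            seed_key = (
                _SEED_EVENTS, ei, cfg.rain_lengths.index(key.rain_length_months),
                cfg.lags.index(key.lag_months), gi,
            )
        else:
            sk = (key.endpoint_month, key.gender)
            seed_key = (_SEED_EVENTS, ei, gi)
        if sk in sims:
            return sims[sk]
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=cfg.seed, spawn_key=seed_key)
        )
        if cfg.exposure == "winter":
            x_true = winter_exposure(unit_daily, field_.dates, windows)
        elif cfg.exposure == "arrangement":
            x_true = unit_window_rainfall(
                unit_daily, field_.dates, [w.rain_interval for w in windows]
            )
        else:
            x_true = np.zeros((lattice.n_units, len(windows)))
        sims[sk] = simulate_events(
            lattice, x_true, truth, windows, gender=key.gender,
            base_rate=cfg.base_rate, rng=rng,
        )
        return sims[sk]

    for idx, key in enumerate(keys):
        kstr = str(key)
        if kstr in manifest["entries"]:
            continue
        windows = window_instances(cfg.study_start, cfg.study_end, key.arrangement)
        sim = get_sim(key, windows)
        z = zmap[key.zonation]
        prepared = aggregate_by_zonation(
            z, sim.counts, sim.populations, unit_daily, field_.dates, windows,
            metadata={
                "arrangement": key.arrangement.label, "zonation": key.zonation,
                "gender": key.gender, "seed": cfg.seed,
            },
        )
        fit_seed = _child_seed(cfg.seed, _SEED_FIT, idx)
        model = BYMModel.from_prepared(prepared, zadj[key.zonation], cfg.bym)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            results = model.fit(seed=fit_seed)
        rr = results.rate_ratio()
        manifest["entries"][kstr] = {
            "endpoint_month": key.endpoint_month,
            "rain_length_months": key.rain_length_months,
            "lag_months": key.lag_months,
            "zonation": key.zonation,
            "gender": key.gender,
            "seed": fit_seed,
            "n_zones": model.n_zones,
            "rr": rr.rr, "ci_low": rr.ci_low, "ci_high": rr.ci_high,
            "rr_scale": rr.scale,
            "warnings": [str(w.message) for w in caught],
        }
        manifest_path.write_text(json.dumps(manifest, indent=2))
        log.info("[%d/%d] %s rr=%.4f (%.4f, %.4f)", idx + 1, len(keys), kstr,
                 rr.rr, rr.ci_low, rr.ci_high)

    manifest["complete"] = len(manifest["entries"]) == len(keys)
    manifest_path.write_text(json.dumps(manifest, indent=2))
    _write_outputs(manifest, out)
    return manifest


def _estimates_by_cell(manifest: dict):
    """Group manifest entries into (arrangement-tuple, gender) -> estimates."""
    from .bym import RateRatioEstimate

    cells: dict = {}
    for entry in manifest["entries"].values():
        cell = (
            entry["endpoint_month"], entry["rain_length_months"],
            entry["lag_months"], entry["gender"],
        )
        cells.setdefault(cell, []).append(
            RateRatioEstimate(
                rr=entry["rr"], ci_low=entry["ci_low"],
                ci_high=entry["ci_high"], scale=entry["rr_scale"],
            )
        )
    return cells


def summarize_manifest(manifest: dict):
    """Arrangement-level consistency grid from a run manifest."""
    from .windows import WindowArrangement

    summaries = []
    for (em, rl, lag, gender), ests in sorted(_estimates_by_cell(manifest).items()):
        summaries.append(
            summarize_arrangement(WindowArrangement(em, rl, lag), gender, ests)
        )
    return build_grid(summaries)


def _write_outputs(manifest: dict, out: Path) -> None:
    import pandas as pd

    entries = manifest["entries"]
    if not entries:
        return
    rows = [
        {
            "arrangement": f"e{v['endpoint_month']:02d}_r{v['rain_length_months']}_l{v['lag_months']:02d}",
            "zonation": v["zonation"], "gender": v["gender"],
            "rr": v["rr"], "ci_low": v["ci_low"], "ci_high": v["ci_high"],
        }
        for v in entries.values()
    ]
    pd.DataFrame(rows).sort_values(["arrangement", "zonation", "gender"]).to_csv(
        out / "rate_ratios.csv", index=False
    )
    grid = summarize_manifest(manifest)
    grid.to_csv(out / "grid.csv", index=False)


def report(manifest: dict) -> str:
    """Human-readable summary of a run manifest."""
    lines = []
    entries = manifest.get("entries", {})
    if not entries:
        warnings.warn("manifest has no entries; nothing to report", stacklevel=2)
        return "empty manifest: no preparations have been run\n"
    if not manifest.get("complete", False):
        warnings.warn("manifest is incomplete; reporting partial results", stacklevel=2)
        lines.append("WARNING: incomplete run — partial report")
    failed = [k for k, v in entries.items() if v.get("warnings")]
    grid = summarize_manifest(manifest)
    lines.append(f"preparations run: {len(entries)}")
    for gender in sorted(grid["gender"].unique()):
        sub = grid[grid["gender"] == gender]
        counts = sub["label"].value_counts().to_dict()
        lines.append(f"{gender}: {len(sub)} arrangement cells — " +
                     ", ".join(f"{k}: {v}" for k, v in sorted(counts.items())))
        for row in sub.itertuples(index=False):
            lines.append(
                f"  {row.endpoint:>9} {row.rain_length}mo lag {row.lag:>2}: "
                f"{row.label:<22} mean RR {row.mean_rr:.4f} (n={row.n_estimates})"
            )
    if failed:
        lines.append(f"fits with sampler warnings: {len(failed)}")
        for k in failed:
            lines.append(f"  {k} (seed {entries[k]['seed']}): {entries[k]['warnings'][0]}")
    return "\n".join(lines) + "\n"
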