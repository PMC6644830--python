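"""Table and configuration I/O plus the end-to-end pipeline.

All tables are TSV with header rows; genomic coordinates are kb, spatial
coordinates nm.  Locus and spot ids are opaque strings; colors are
strings drawn from one shared palette.  Reports are JSON and carry the
config hash and seed so reruns are reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import engine, metrics, penalties, polymer, series
from .dna_model import DnaModelParams

__all__ = [
    "RunConfig",
    "read_config",
    "read_loci",
    "read_mapping_table",
    "read_problem",
    "read_spots",
    "read_truth",
    "run_pipeline",
    "write_loci",
    "write_mapping_table",
    "write_spots",
    "write_truth",
]

MISSING_TOKEN = "MISSING"


# ---------------------------------------------------------------- tables

def write_loci(path, track: polymer.LocusTrack, palette: list[str]) -> None:
    df = pd.DataFrame(
        {
            "locus_id": list(track.ids),
            "genomic_kb": track.genomic_kb,
            "color": [palette[c] for c in track.colors],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def write_spots(path, field: polymer.SpotField, palette: list[str]) -> None:
    df = pd.DataFrame(
        {
            "spot_id": list(field.ids),
            "x_nm": field.xyz[:, 0],
            "y_nm": field.xyz[:, 1],
            "z_nm": field.xyz[:, 2],
            "color": [palette[c] for c in field.colors],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def write_truth(path, truth: polymer.GroundTruth, track, field) -> None:
    rows = []
    for i, s in enumerate(truth.true_mapping):
        rows.append(
            {
                "locus_id": track.ids[i],
                "spot_id": field.ids[s] if s != polymer.MISSING else MISSING_TOKEN,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_loci(path, palette: list[str] | None = None):
    df = pd.read_csv(path, sep="\t", dtype={"locus_id": str, "color": str})
    if df["genomic_kb"].isna().any():
        raise ValueError(f"{path}: NaN genomic coordinate")
    if not df["genomic_kb"].is_monotonic_increasing:
        warnings.warn(f"{path}: loci not sorted by genomic coordinate; sorting")
        df = df.sort_values("genomic_kb", kind="stable").reset_index(drop=True)
    colors = df["color"].astype(str).tolist()
    if palette is None:
        palette = sorted(set(colors))
    bad = set(colors) - set(palette)
    if bad:
        raise ValueError(f"{path}: colors outside palette: {sorted(bad)}")
    idx = {c: i for i, c in enumerate(palette)}
    track = polymer.LocusTrack(
        df["genomic_kb"].to_numpy(float),
        np.array([idx[c] for c in colors], dtype=int),
        n_colors=len(palette),
        ids=tuple(df["locus_id"].astype(str)),
    )
    return track, palette


def read_spots(path, palette: list[str]):
    df = pd.read_csv(path, sep="\t", dtype={"spot_id": str, "color": str})
    xyz = df[["x_nm", "y_nm", "z_nm"]].to_numpy(float)
    if np.isnan(xyz).any():
        raise ValueError(f"{path}: NaN spot coordinate")
    colors = df["color"].astype(str).tolist()
    bad = set(colors) - set(palette)
    if bad:
        raise ValueError(f"{path}: spot colors outside palette: {sorted(bad)}")
    idx = {c: i for i, c in enumerate(palette)}
    return polymer.SpotField(
        xyz,
        np.array([idx[c] for c in colors], dtype=int),
        n_colors=len(palette),
        ids=tuple(df["spot_id"].astype(str)),
    )


def read_truth(path, track, field) -> np.ndarray:
    df = pd.read_csv(path, sep="\t", dtype=str)
    by_locus = dict(zip(df["locus_id"], df["spot_id"]))
    spot_idx = {sid: i for i, sid in enumerate(field.ids)}
    out = np.full(len(track), polymer.MISSING, dtype=int)
    for i, lid in enumerate(track.ids):
        sid = by_locus.get(lid, MISSING_TOKEN)
        out[i] = polymer.MISSING if sid == MISSING_TOKEN else spot_idx[sid]
    return out


def write_mapping_table(path, table: engine.MappingTable, track, field) -> None:
    df = pd.DataFrame(table.probs, columns=list(field.ids) + [MISSING_TOKEN])
    df.insert(0, "locus_id", list(track.ids))
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_mapping_table(path) -> engine.MappingTable:
    df = pd.read_csv(path, sep="\t")
    return engine.MappingTable(df.drop(columns=["locus_id"]).to_numpy(float))


def read_problem(
    loci_path,
    spots_path,
    model: DnaModelParams,
    palette: list[str] | None = None,
    p_fn_targets=None,
    p_extra: float = 0.1,
) -> engine.ProblemSpec:
    """Load and validate a problem from loci/spots tables."""
    track, palette = read_loci(loci_path, palette)
    spots = read_spots(spots_path, palette)
    if p_fn_targets is None:
        p_fn_targets = engine.missing_rate_targets(track, spots, p_extra)
    return engine.ProblemSpec(track, spots, model, p_fn_targets=p_fn_targets)


# ---------------------------------------------------------------- config

@dataclass
class SimConfig:
    n_l: float = 0.3          # kb/nm
    l_p: float = 300.0        # kb
    contour_kb: float = 10_000.0
    step_kb: float = 25.0
    label_density_per_mb: float = 1.0
    n_colors: int = 3
    sigma_xy: float = 100.0
    sigma_z: float = 200.0
    p_fn: float = 0.1
    p_extra: float = 0.1


@dataclass
class ModelConfig:
    n_l: float = 0.3
    l_p: float = 300.0
    rho: float = 0.5
    loc_var_nm2: float = 0.0


@dataclass
class OptimizerConfig:
    enabled: bool = True
    max_iter_missing: int = 40
    cycles: int = 6
    max_iter_spot: int = 50
    max_iter_polish: int = 30
    gamma_missing: float = 0.8
    gamma_spot: float = 0.7
    polish: bool = True


@dataclass
class SeriesConfig:
    enabled: bool = False
    mode: str = "series2"
    n_psi: int = 0            # explicit mapping/constraint budget ...
    min_terms: int = 0        # ... or grow until this many terms
    max_order: int | None = None
    term_cap: int = 200_000   # hard cap on closed-term enumeration
    term_budget: int = 0      # evaluate only the top-|w*magnitude| terms (0: all)


@dataclass
class RunConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    optimizer: OptimizerConfig = field(default_factory=OptimizerConfig)
    series: SeriesConfig = field(default_factory=SeriesConfig)
    seed: int = 0
    outdir: str = "locimap_run"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def read_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = RunConfig()
    for section, cls in [
        ("sim", SimConfig),
        ("model", ModelConfig),
        ("optimizer", OptimizerConfig),
        ("series", SeriesConfig),
    ]:
        if section in raw:
            setattr(cfg, section, cls(**raw[section]))
    for key in ("seed", "outdir"):
        if key in raw:
            setattr(cfg, key, raw[key])
    return cfg


def write_config(path, cfg: RunConfig) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)


# ---------------------------------------------------------------- pipeline

def model_from_config(cfg: RunConfig) -> DnaModelParams:
    return DnaModelParams(cfg.model.n_l, cfg.model.l_p, cfg.model.rho,
                          cfg.model.loc_var_nm2)


def simulate_experiment(cfg: RunConfig, seed=None):
    """Simulate one experiment per the config; returns (spec, truth, palette)."""
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    s = cfg.sim
    conf = polymer.simulate_wlc(s.n_l, s.l_p, s.contour_kb, s.step_kb,
                                rng.integers(2**63))
    track, xyz = polymer.place_labels(conf, s.label_density_per_mb, s.n_colors,
                                      rng.integers(2**63))
    err = polymer.ErrorModel(s.sigma_xy, s.sigma_z, s.p_fn, s.p_extra)
    field_, truth = polymer.render_image(xyz, track.colors, s.n_colors, err,
                                         rng.integers(2**63))
    palette = [f"c{i}" for i in range(s.n_colors)]
    targets = engine.missing_rate_targets(track, field_, s.p_extra)
    spec = engine.ProblemSpec(track, field_, model_from_config(cfg),
                              p_fn_targets=targets)
    return spec, truth, palette


def infer(spec: engine.ProblemSpec, cfg: RunConfig):
    """Baseline -> optional penalty optimization -> optional series.

    Returns (table, estimate, info dict).
    """
    info: dict = {"converged": None, "n_terms": 1}
    if cfg.optimizer.enabled:
        settings = penalties.OptimizerSettings(
            max_iter_missing=cfg.optimizer.max_iter_missing,
            cycles=cfg.optimizer.cycles,
            max_iter_spot=cfg.optimizer.max_iter_spot,
            max_iter_polish=cfg.optimizer.max_iter_polish,
            gamma_missing=cfg.optimizer.gamma_missing,
            gamma_spot=cfg.optimizer.gamma_spot,
            polish=cfg.optimizer.polish,
        )
        opt = penalties.optimize(spec, settings=settings)
        spec = penalties.replace_penalties(spec, opt.penalties)
        table, est = opt.table, opt.estimate
        info["converged"] = opt.converged
        info["n_iterations"] = opt.n_iterations
    else:
        est = engine.evaluate_term(spec)
        table = engine.mapping_probabilities(est)

    if cfg.series.enabled:
        sc = cfg.series
        if sc.min_terms > 0:
            sel = series.select_terms_by_count(
                table, spec, sc.mode, sc.min_terms, sc.max_order, sc.term_cap,
                max_terms=sc.term_budget or None)
        else:
            sel = series.select_terms(table, spec, sc.mode, sc.n_psi,
                                      sc.max_order, sc.term_cap)
        res = series.evaluate_series(spec, sel)
        est = res.estimate
        table = engine.mapping_probabilities(est)
        info["n_terms"] = res.n_terms
        info["n_psi"] = sel.n_psi
    return table, est, info


def run_pipeline(cfg: RunConfig, outdir=None) -> dict:
    """simulate -> infer -> evaluate -> call; writes all artifacts to disk."""
    out = Path(outdir or cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"config_hash": cfg.config_hash(), "seed": cfg.seed}

    spec, truth, palette = simulate_experiment(cfg)
    write_loci(out / "loci.tsv", spec.loci, palette)
    write_spots(out / "spots.tsv", spec.spots, palette)
    write_truth(out / "truth.tsv", truth, spec.loci, spec.spots)
    write_config(out / "config.yaml", cfg)

    table, est, info = infer(spec, cfg)
    write_mapping_table(out / "mapping.tsv", table, spec.loci, spec.spots)

    report = metrics.quality_report(table, truth.true_mapping, exclude_zero=True)
    called = metrics.contour_accuracy(metrics.call_conformation(table),
                                      truth.true_mapping)
    call_rows = [
        {
            "locus_id": spec.loci.ids[i],
            "spot_id": spec.spots.ids[s] if s != polymer.MISSING else MISSING_TOKEN,
        }
        for i, s in enumerate(called.assignment)
    ]
    pd.DataFrame(call_rows).to_csv(out / "called.tsv", sep="\t", index=False)

    summary = {
        **meta,
        "log_Z": est.log_Z,
        "unrecovered_bits": report.unrecovered_bits,
        "entropy_bits": report.entropy_bits,
        "excluded_loci": report.excluded_loci,
        "baseline_uncertainty_bits": engine.baseline_uncertainty(spec),
        "alignment_errors": called.n_alignment_errors,
        "contour_accuracy": called.accuracy,
        **info,
    }
    with open(out / "report.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    return summary
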