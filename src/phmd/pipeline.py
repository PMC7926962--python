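"""Config-driven orchestration of the toy prediction workflow.

The stages mirror the full strategy for predicting pH-dependent antibody
binding at desk scale: identify key cross-CDR residues, minimize, collect
unbiased potential statistics, run boosted constant-pH production per pH,
reweight to a 2D PMF over (BRRMSD, D3), extract and classify low-PMF
conformational states, run plain constant-pH production for D3 profiles,
titrate the model compound, and write a human-readable report.

Every stage writes CSV/JSON outputs into the configured output directory
and is seeded deterministically from the master seed (numpy SeedSequence
spawned per stage name), so a rerun with the same config reproduces every
output file.
"""

from __future__ import annotations

import dataclasses
import json
import tomllib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import cphmd as cphmd_mod
from . import gamd as gamd_mod
from .engine import PotentialStats, SimulationConfig, minimize, run_cmd
from .reweighting import edges_from_widths, reweight_cumulant2
from .structure import (
    classify_states,
    extract_states,
    filter_states,
    key_residue_pairs,
    load_example_state_table,
    superposed_rmsd,
)
from .toy_systems import (
    FabLayout,
    HarmonicNetworkSystem,
    make_fab_fixture,
    make_mini_fab,
    make_titratable_compound,
)


class PipelineError(RuntimeError):
    pass


_STAGES = ("prep", "minimize", "cmd_stats", "gamd", "reweight", "states",
           "classify", "cphmd", "titrate", "report")


@dataclass
class PipelineConfig:
    """Everything a full toy run needs; see docs for per-field meaning."""

    outdir: str = "phmd_out"
    master_seed: int = 1
    ph_list: tuple = (6.0, 7.4)
    fixture_mode: bool = False        # classify the packaged state tables instead of a fresh run

    # toy system
    n_residues_per_loop: int = 5
    loop_separation: float = 12.0
    site_pka_model: float = 6.0
    site_delta_pka: float = 0.0

    # engine
    temperature: float = 310.0
    timestep: float = 0.002
    friction: float = 5.0
    record_interval: int = 20
    cmd_steps: int = 20000
    gamd_equil_steps: int = 20000
    gamd_production_steps: int = 60000
    cphmd_production_steps: int = 40000

    # gamd
    sigma0: float = 10.0
    threshold_mode: str = "lower"
    refresh_interval: int = 250

    # cphmd
    barrier_height: float = 2.0
    barrier_form: str = "penalize-intermediate"
    lambda_mass: float = 10.0
    titration_ph: tuple = (4.5, 5.5, 6.5, 7.5)
    titration_steps: int = 100000

    # analysis thresholds
    pmf_cutoff: float = 50.0
    bind_max: float = 1.5
    nonbind_min: float = 2.5
    key_residue_cutoff: float = 10.0
    bin_widths: tuple = (0.5, 1.0)

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        flat: dict = {}
        for key, value in raw.items():
            if isinstance(value, dict):
                flat.update(value)
            else:
                flat[key] = value
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(flat) - names
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        for k, v in flat.items():
            if isinstance(v, list):
                flat[k] = tuple(v)
        cfg = cls(**flat)
        if not cfg.ph_list:
            raise PipelineError("ph_list must be non-empty")
        return cfg

    def stage_seed(self, stage: str, index: int = 0) -> int:
        """Deterministic per-stage seed fan-out from the master seed."""
        if stage not in _STAGES:
            raise PipelineError(f"unknown stage {stage!r}")
        key = (_STAGES.index(stage), index)
        ss = np.random.SeedSequence(self.master_seed, spawn_key=key)
        return int(ss.generate_state(1)[0] % (2**31))


def _ph_tag(ph: float) -> str:
    return f"{ph:g}".replace(".", "p")


@dataclass
class PipelineResult:
    config: PipelineConfig
    outputs: dict = field(default_factory=dict)      # stage -> list of written paths
    state_tables: dict = field(default_factory=dict)  # ph -> DataFrame
    classifications: dict = field(default_factory=dict)
    titration: Optional[dict] = None
    provenance: str = "fresh run"
    seeds: dict = field(default_factory=dict)

    def record(self, stage: str, *paths) -> None:
        self.outputs.setdefault(stage, []).extend(str(p) for p in paths)


class _Workspace:
    """In-memory handles shared between stages of one run."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        self.outdir = Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.model = make_mini_fab(
            n_residues_per_loop=config.n_residues_per_loop,
            seed=config.stage_seed("prep"),
            loop_separation=config.loop_separation,
        )
        # protonated: like charges across the paratope (repulsion distorts the
        # loops); deprotonated: neutral, native geometry
        self.site = make_titratable_compound(
            config.site_pka_model, config.site_delta_pka, temperature=config.temperature,
            q_protonated=(0.7, 0.3), q_deprotonated=(0.0, 0.0),
        )
        self.system = HarmonicNetworkSystem(self.model, site=self.site)
        i, j = self.system.site_beads
        r_site = float(np.linalg.norm(self.model.coords0[i] - self.model.coords0[j]))
        self.site_compound = replace(self.site, bond_r0=r_site)
        self.reference: Optional[np.ndarray] = None
        self.stats: Optional[PotentialStats] = None
        self.fit: Optional[cphmd_mod.ModelCompoundFit] = None

    def engine_config(self, n_steps: int, seed: int) -> SimulationConfig:
        c = self.config
        return SimulationConfig(
            temperature=c.temperature, timestep=c.timestep, friction=c.friction,
            n_steps=n_steps, record_interval=c.record_interval, seed=seed,
        )

    def cphmd_config(self, ph: float) -> cphmd_mod.CpHMDConfig:
        c = self.config
        return cphmd_mod.CpHMDConfig(
            ph=ph, barrier_height=c.barrier_height, barrier_form=c.barrier_form,
            lambda_mass=c.lambda_mass, temperature=c.temperature,
        )

    def require(self, attr: str, stage: str, needed_by: str):
        value = getattr(self, attr)
        if value is None:
            raise PipelineError(f"stage {needed_by!r} requires outputs of stage {stage!r}")
        return value


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage in order and return the collected results."""
    return run_until(config, "report")


def run_until(config: PipelineConfig, stage: str) -> PipelineResult:
    """Run stages in order up to and including ``stage``.

    Stage order: prep, minimize, cmd_stats, gamd, reweight/states, classify,
    cphmd, titrate, report.  In fixture mode only classification of the
    packaged state tables and the report run.
    """
    if stage not in _STAGES:
        raise PipelineError(f"unknown stage {stage!r}")
    ws = _Workspace(config)
    result = PipelineResult(config=config)
    if config.fixture_mode:
        _classify_fixture(ws, result)
        stage_report(ws, result)
        return result
    target = _STAGES.index(stage)
    rc_tables: dict = {}
    stage_prep(ws, result)
    if target >= _STAGES.index("minimize"):
        stage_minimize(ws, result)
    if target >= _STAGES.index("cmd_stats"):
        stage_cmd_stats(ws, result)
    if target >= _STAGES.index("gamd"):
        rc_tables = stage_gamd(ws, result)
    if target >= _STAGES.index("reweight"):
        stage_reweight_states(ws, result, rc_tables)
    if target >= _STAGES.index("classify"):
        stage_classify(ws, result)
    if target >= _STAGES.index("cphmd"):
        stage_cphmd(ws, result)
    if target >= _STAGES.index("titrate"):
        stage_titrate(ws, result)
    if target >= _STAGES.index("report"):
        stage_report(ws, result)
    return result


# --------------------------------------------------------------------------
# individual stages
# --------------------------------------------------------------------------

def stage_prep(ws: _Workspace, result: PipelineResult) -> None:
    """Build the toy system, PDB fixture and the key-residue table (10 A rule)."""
    cfg = ws.config
    fab = make_fab_fixture(FabLayout(include_antigen=True))
    pdb_path = ws.outdir / "fab_fixture.pdb"
    fab.to_pdb(pdb_path)
    pairs = key_residue_pairs(fab, cutoff=cfg.key_residue_cutoff)
    pairs_path = ws.outdir / "key_residues.csv"
    pairs.to_csv(pairs_path, index=False)
    ref_path = ws.outdir / "minifab_reference.csv"
    pd.DataFrame(ws.model.coords0, columns=["x", "y", "z"]).to_csv(ref_path, index=False)
    result.record("prep", pdb_path, pairs_path, ref_path)
    result.seeds["prep"] = cfg.stage_seed("prep")


def stage_minimize(ws: _Workspace, result: PipelineResult) -> None:
    """Energy-minimize the toy system; the minimum is the BRRMSD reference."""
    res = minimize(ws.system, lambda_values=np.array([1.0]))
    ws.reference = res.coords.reshape(-1, 3)
    path = ws.outdir / "minimized_coords.csv"
    pd.DataFrame(ws.reference, columns=["x", "y", "z"]).to_csv(path, index=False)
    result.record("minimize", path)


def stage_cmd_stats(ws: _Workspace, result: PipelineResult) -> None:
    """Unbiased MD for the initial Vmax/Vmin/Vave/sigmaV statistics."""
    seed = ws.config.stage_seed("cmd_stats")
    cfg = ws.engine_config(ws.config.cmd_steps, seed)
    out = run_cmd(ws.system, cfg, x0=ws.require("reference", "minimize", "cmd_stats").ravel(),
                  lambda_values=np.array([1.0]))
    ws.stats = out.stats
    path = ws.outdir / "cmd_stats.json"
    s = out.stats
    path.write_text(json.dumps(
        {"vmax": s.vmax, "vmin": s.vmin, "vave": s.vave, "sigma_v": s.sigma_v,
         "n_samples": s.n_samples, "seed": seed}, indent=2))
    result.record("cmd_stats", path)
    result.seeds["cmd_stats"] = seed


def _measure_rc(ws: _Workspace, coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame (BRRMSD, D3) of mini-Fab coordinates against the reference."""
    model = ws.model
    ref = ws.require("reference", "minimize", "gamd")
    idx = np.concatenate([model.loops[r] for r in sorted(model.loops)])
    rc1 = np.empty(coords.shape[0])
    rc2 = np.empty(coords.shape[0])
    for k in range(coords.shape[0]):
        xyz = coords[k].reshape(-1, 3)
        rc1[k] = superposed_rmsd(xyz[idx], ref[idx])
        a = (xyz[model.loops["HCDR3-like"]]).mean(axis=0)
        b = (xyz[model.loops["LCDR3-like"]]).mean(axis=0)
        rc2[k] = float(np.linalg.norm(a - b))
    return rc1, rc2


def stage_gamd(ws: _Workspace, result: PipelineResult) -> dict:
    """Boosted constant-pH production per pH; writes (rc1, rc2, dV) tables."""
    cfg = ws.config
    stats = ws.require("stats", "cmd_stats", "gamd")
    ws.fit = cphmd_mod.fit_model_compound(
        ws.site_compound, seed=cfg.stage_seed("gamd", 99)
    )
    params = gamd_mod.GaMDParams.adapt(stats, cfg.sigma0, cfg.threshold_mode)
    params.validate()
    tables = {}
    for k, ph in enumerate(cfg.ph_list):
        seed = cfg.stage_seed("gamd", k)
        engine = ws.engine_config(cfg.gamd_equil_steps + cfg.gamd_production_steps, seed)
        run = cphmd_mod.run_cphmd(
            ws.system, ph, ws.cphmd_config(ph), engine, ws.fit,
            x0=ws.reference.ravel(), gamd_params=params,
        )
        n_equil = cfg.gamd_equil_steps // cfg.record_interval
        coords = run.coords[n_equil:]
        dv = run.boost[n_equil:]
        rc1, rc2 = _measure_rc(ws, coords)
        df = pd.DataFrame({"frame": np.arange(rc1.size), "rc1": rc1, "rc2": rc2, "dv": dv})
        path = ws.outdir / f"traj_ph{_ph_tag(ph)}.csv"
        df.to_csv(path, index=False)
        tables[ph] = df
        result.record("gamd", path)
        result.seeds[f"gamd_ph{_ph_tag(ph)}"] = seed
    return tables


def stage_reweight_states(ws: _Workspace, result: PipelineResult, rc_tables: dict) -> None:
    """Cumulant reweighting to 2D PMF grids and low-PMF state extraction."""
    cfg = ws.config
    for ph, df in rc_tables.items():
        lo1, hi1 = 0.0, float(np.ceil(df["rc1"].max() / cfg.bin_widths[0]) * cfg.bin_widths[0]) + cfg.bin_widths[0]
        lo2 = float(np.floor(df["rc2"].min() / cfg.bin_widths[1]) * cfg.bin_widths[1])
        hi2 = float(np.ceil(df["rc2"].max() / cfg.bin_widths[1]) * cfg.bin_widths[1]) + cfg.bin_widths[1]
        edges = edges_from_widths(((lo1, hi1), (lo2, hi2)), cfg.bin_widths)
        grid = reweight_cumulant2(df, edges, temperature=cfg.temperature)
        grid_path = ws.outdir / f"pmf_grid_ph{_ph_tag(ph)}.csv"
        grid.write_csv(grid_path)
        table = extract_states(grid, pmf_cutoff=cfg.pmf_cutoff)
        table_path = ws.outdir / f"states_ph{_ph_tag(ph)}.csv"
        table.to_csv(table_path, index=False)
        result.state_tables[ph] = table
        result.record("reweight", grid_path)
        result.record("states", table_path)


def stage_classify(ws: _Workspace, result: PipelineResult) -> None:
    """Binder / non-binder classification of each per-pH state table."""
    cfg = ws.config
    rows = []
    for ph, table in result.state_tables.items():
        counts = classify_states(table, bind_max=cfg.bind_max, nonbind_min=cfg.nonbind_min)
        result.classifications[ph] = counts
        rows.append({"ph": ph, "binder_like": counts.binder_like,
                     "non_binder_like": counts.non_binder_like,
                     "indeterminate": counts.indeterminate, "total": counts.total})
    path = ws.outdir / "classification.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    result.record("classify", path)


def _classify_fixture(ws: _Workspace, result: PipelineResult) -> None:
    cfg = ws.config
    result.provenance = "packaged table"
    rows = []
    for ph in cfg.ph_list:
        table = load_example_state_table(ph)
        table = filter_states(table, pmf_cutoff=cfg.pmf_cutoff)
        counts = classify_states(table, bind_max=cfg.bind_max, nonbind_min=cfg.nonbind_min)
        result.state_tables[ph] = table
        result.classifications[ph] = counts
        rows.append({"ph": ph, "binder_like": counts.binder_like,
                     "non_binder_like": counts.non_binder_like,
                     "indeterminate": counts.indeterminate, "total": counts.total})
    path = ws.outdir / "classification.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    result.record("classify", path)


def stage_cphmd(ws: _Workspace, result: PipelineResult) -> None:
    """Plain constant-pH production per pH: D3 profiles and lambda logs."""
    cfg = ws.config
    if ws.fit is None:
        ws.fit = cphmd_mod.fit_model_compound(ws.site_compound, seed=cfg.stage_seed("gamd", 99))
    for k, ph in enumerate(cfg.ph_list):
        seed = cfg.stage_seed("cphmd", k)
        engine = ws.engine_config(cfg.cphmd_production_steps, seed)
        run = cphmd_mod.run_cphmd(
            ws.system, ph, ws.cphmd_config(ph), engine, ws.fit, x0=ws.reference.ravel()
        )
        _, d3 = _measure_rc(ws, run.coords)
        prof = pd.DataFrame({"frame": np.arange(d3.size), "d3": d3})
        prof_path = ws.outdir / f"d3_profile_ph{_ph_tag(ph)}.csv"
        prof.to_csv(prof_path, index=False)
        lam_path = ws.outdir / f"lambda_log_ph{_ph_tag(ph)}.csv"
        run.lambda_log().to_csv(lam_path, index=False)
        result.record("cphmd", prof_path, lam_path)
        result.seeds[f"cphmd_ph{_ph_tag(ph)}"] = seed


def stage_titrate(ws: _Workspace, result: PipelineResult) -> None:
    """Titration of the site's model compound and pKa fit."""
    cfg = ws.config
    seed = cfg.stage_seed("titrate")
    engine = ws.engine_config(cfg.titration_steps, seed)
    curve = cphmd_mod.titrate(
        ws.site_compound, cfg.titration_ph,
        config=ws.cphmd_config(cfg.titration_ph[0]),
        engine_config=engine, seeds=(seed,), fit=ws.fit,
    )
    pka = cphmd_mod.fit_pka(curve)
    curve_path = ws.outdir / "titration.csv"
    curve.to_frame().to_csv(curve_path, index=False)
    pka_path = ws.outdir / "pka.json"
    pka_path.write_text(json.dumps(
        {"pka": pka.pka, "hill": pka.hill, "rss": pka.rss,
         "apparent_pka_constructed": ws.site.apparent_pka}, indent=2))
    result.titration = {"curve": curve, "fit": pka}
    result.record("titrate", curve_path, pka_path)
    result.seeds["titrate"] = seed


def report(result: PipelineResult) -> str:
    """Human-readable run summary naming every threshold and seed used."""
    if not result.state_tables and result.titration is None and not result.outputs:
        raise PipelineError("no completed stages to report")
    cfg = result.config
    lines = [
        "pH-dependent binding prediction - toy run summary",
        "=" * 52,
        f"data provenance: {result.provenance}",
        f"master seed: {cfg.master_seed}",
        f"thresholds: PMF cutoff {cfg.pmf_cutoff} kcal/mol; binder-like BRRMSD <= "
        f"{cfg.bind_max} A; non-binder-like BRRMSD >= {cfg.nonbind_min} A; "
        f"key-residue COM distance < {cfg.key_residue_cutoff} A",
        "",
    ]
    if result.classifications:
        lines.append("conformational states by pH (side-by-side):")
        header = "  pH      states  binder-like  non-binder-like  indeterminate"
        lines.append(header)
        for ph in sorted(result.classifications):
            c = result.classifications[ph]
            lines.append(f"  {ph:<7g} {c.total:^7d} {c.binder_like:^11d} "
                         f"{c.non_binder_like:^15d} {c.indeterminate:^13d}")
        lines.append("")
    if result.titration is not None:
        fit = result.titration["fit"]
        lines.append(f"titration: fitted pKa = {fit.pka:.2f} (Hill n = {fit.hill:.2f})")
        lines.append("")
    if result.seeds:
        lines.append("stage seeds: " + ", ".join(f"{k}={v}" for k, v in sorted(result.seeds.items())))
    return "\n".join(lines) + "\n"


def stage_report(ws: _Workspace, result: PipelineResult) -> None:
    text = report(result)
    path = ws.outdir / "report.txt"
    path.write_text(text)
    summary_rows = [
        {"ph": ph, "binder_like": c.binder_like, "non_binder_like": c.non_binder_like,
         "indeterminate": c.indeterminate}
        for ph, c in sorted(result.classifications.items())
    ]
    csv_path = ws.outdir / "summary.csv"
    pd.DataFrame(summary_rows).to_csv(csv_path, index=False)
    result.record("report", path, csv_path)
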