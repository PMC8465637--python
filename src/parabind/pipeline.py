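"""End-to-end orchestration: generate synthetic inputs, run every analysis
stage, and emit a deterministic JSON report with TSV/CSV side tables.

A single global seed deterministically derives an independent substream per
stage (keyed by stage name), so adding or removing a stage never reshuffles
the randomness of the others.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import __version__, binding, flexibility, geometry, motifs, synthetic, thermal

__all__ = [
    "ConfigError",
    "StageError",
    "PipelineConfig",
    "PipelineReport",
    "parse_quantity",
    "validate_config",
    "run_pipeline",
    "stage_seed",
]

log = logging.getLogger("parabind")

STAGES = ("motifs", "spr", "isotherms", "geometry", "flexibility", "thermal")

_TOP_KEYS = {"seed", "outdir", "stages", "report_format"}
_STAGE_KEYS: dict[str, set[str]] = {
    "motifs": {"fasta", "consensus", "max_mismatch", "spacer_min", "spacer_max",
               "left_margin_threshold"},
    "spr": {"noise_sd", "true_dimers_bound", "rl_immobilized", "bp_ligand",
            "mw_analyte", "ka_true", "kd_true"},
    "isotherms": {"scenarios", "noise_sd"},
    "geometry": {"center_sep_bp", "span_nm", "bend_max_deg", "bend_step_deg",
                 "rise_nm", "bp_per_turn"},
    "flexibility": {"n_frames", "n_residues", "core_sigma", "loop_sigma",
                    "loop_interval", "marker_residue", "marker_displacement"},
    "thermal": {"conditions", "dH_vant_hoff", "noise_sd", "smooth_window_C"},
}

_UNIT_SCALE = {
    "m": 1.0, "mm": 1e-3, "um": 1e-6, "µm": 1e-6, "nm": 1e-9, "pm": 1e-12,
}


class ConfigError(ValueError):
    """Invalid or unknown pipeline configuration."""


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def parse_quantity(text: str) -> float:
    """Normalize a unit-suffixed quantity string to base units.

    Concentrations collapse to molar ("85 nM" -> 8.5e-8), temperatures to
    deg C ("44.5 C"), times to seconds, lengths in bp pass through.  Bare
    numbers are returned unchanged.
    """
    s = text.strip()
    m = re.fullmatch(r"([-+0-9.eE]+)\s*([^\s]*)", s)
    if not m:
        raise ConfigError(f"cannot parse quantity {text!r}")
    value = float(m.group(1))
    unit = m.group(2)
    if unit == "":
        return value
    low = unit.lower()
    if low in _UNIT_SCALE:
        return value * _UNIT_SCALE[low]
    if low in {"c", "°c", "degc"}:
        return value
    if low in {"s", "sec"}:
        return value
    if low in {"min"}:
        return value * 60.0
    if low in {"bp", "ru", "da"}:
        return value
    raise ConfigError(f"unknown unit {unit!r} in {text!r}")


@dataclass
class PipelineConfig:
    seed: int | None = None
    outdir: str = "parabind_out"
    stages: dict[str, dict] = field(default_factory=dict)
    report_format: str = "json"

    def canonical_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "outdir": self.outdir,
                "stages": self.stages,
                "report_format": self.report_format,
            },
            sort_keys=True,
        )

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()[:16]


@dataclass
class PipelineReport:
    stages: dict[str, dict]
    skipped: list[str]
    seed: int | None
    config_hash: str
    version: str

    def to_dict(self) -> dict:
        return {
            "stages": self.stages,
            "skipped": self.skipped,
            "seed": self.seed,
            "config_hash": self.config_hash,
            "version": self.version,
        }


def validate_config(source: str | Path | dict) -> PipelineConfig:
    """Load, schema-check and normalize a pipeline configuration.

    Unknown keys raise a :class:`ConfigError` naming the key; unit-suffixed
    string values are normalized to numbers; stage sections default to all
    stages with default parameters when ``stages`` is omitted.
    """
    if isinstance(source, (str, Path)):
        p = Path(source)
        if not p.exists():
            raise ConfigError(f"config file not found: {p}")
        raw = json.loads(p.read_text())
    else:
        raw = dict(source)
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    stages_raw = raw.get("stages")
    if stages_raw is None:
        stages_raw = {name: {} for name in STAGES}
    if not isinstance(stages_raw, dict):
        raise ConfigError("'stages' must be a mapping of stage name -> params")
    stages: dict[str, dict] = {}
    for name, params in stages_raw.items():
        if name not in _STAGE_KEYS:
            raise ConfigError(f"unknown stage {name!r}; known: {list(STAGES)}")
        if params is None:
            params = {}
        bad = set(params) - _STAGE_KEYS[name]
        if bad:
            raise ConfigError(f"unknown key(s) in stage {name!r}: {sorted(bad)}")
        norm = {}
        for k, v in params.items():
            if isinstance(v, str) and re.match(r"^[-+0-9.]", v.strip()):
                try:
                    norm[k] = parse_quantity(v)
                    continue
                except ConfigError:
                    pass
            norm[k] = v
        stages[name] = norm
    seed = raw.get("seed")
    if seed is not None and (not isinstance(seed, int) or isinstance(seed, bool)):
        raise ConfigError("'seed' must be an integer")
    needs_seed = any(
        not (name == "geometry" or (name == "motifs" and "fasta" in params))
        for name, params in stages.items()
    )
    if needs_seed and seed is None:
        raise ConfigError("'seed' is required when any generator stage runs")
    return PipelineConfig(
        seed=seed,
        outdir=str(raw.get("outdir", "parabind_out")),
        stages=stages,
        report_format=str(raw.get("report_format", "json")),
    )


def stage_seed(global_seed: int, stage: str) -> int:
    """Stage-keyed deterministic substream seed (stable across stage sets)."""
    return int((zlib.crc32(stage.encode()) ^ (global_seed * 2654435761)) % 2**31)


# ---------------------------------------------------------------------------
# Stage runners


def _run_motifs(cfg: dict, seed: int, outdir: Path) -> dict:
    consensus = cfg.get("consensus", "CTTTGC")
    max_mm = int(cfg.get("max_mismatch", 2))
    if "fasta" in cfg:
        seqs = motifs.read_fasta(cfg["fasta"])
        if not seqs:
            raise FileNotFoundError(f"no sequences in {cfg['fasta']}")
        seq_id, seq = next(iter(seqs.items()))
    else:
        arch = synthetic.default_f_architecture()
        seq, truth = synthetic.build_promoter_sequence(arch, seed)
        seq_id = "PparAB_synthetic"
        synthetic.write_promoter_fasta(seq, outdir / "promoter.fasta", seq_id)
        truth.to_csv(outdir / "promoter_truth.tsv", sep="\t", index=False)
    hits = motifs.scan_motifs(seq, consensus, max_mm, seq_id=seq_id)
    pairs = motifs.find_inverted_repeats(
        hits,
        spacer_min=int(cfg.get("spacer_min", 26)),
        spacer_max=int(cfg.get("spacer_max", 29)),
    )
    report = motifs.classify_architecture(
        hits, pairs, len(seq),
        left_margin_threshold=int(cfg.get("left_margin_threshold", 40)),
    )
    motifs.write_hits_bed(hits, outdir / "motif_hits.bed")
    motifs.write_architecture_json(report, outdir / "architecture.json")
    perfect = [p for p in pairs if p.irclass == "perfect"]
    return {
        "n_hits": len(hits),
        "n_exact_hits": sum(1 for h in hits if h.mismatches == 0),
        "n_ir_pairs": len(pairs),
        "perfect_spacer": perfect[0].spacer if perfect else None,
        "perfect_center_distance": perfect[0].center_distance if perfect else None,
        "n_overlaps": len(report.overlaps),
        "architecture": report.to_dict(),
    }


def _run_spr(cfg: dict, seed: int, outdir: Path) -> dict:
    scen = synthetic.default_spr_scenario(seed=seed, **{
        k: v for k, v in cfg.items()
    })
    curves = synthetic.simulate_sensorgrams(scen)
    synthetic.write_sensorgrams_csv(curves, outdir / "sensorgrams.csv")
    fit = binding.fit_kinetics(curves)
    st = binding.stoichiometry(
        fit.params.rmax, scen.mw_analyte, scen.mw_ligand, scen.rl_immobilized
    )
    result = {
        "ka": fit.params.ka,
        "kd": fit.params.kd,
        "KD_M": fit.params.KD,
        "rmax_RU": fit.params.rmax,
        "s_monomers": st.s_monomers,
        "s_dimers": st.s_dimers,
    }
    (outdir / "kinetics.json").write_text(json.dumps(result, indent=2) + "\n")
    return result


def _run_isotherms(cfg: dict, seed: int, outdir: Path) -> dict:
    wanted = cfg.get("scenarios", ["emsa", "mst", "parb"])
    makers = {
        "emsa": synthetic.default_emsa_scenario,
        "mst": synthetic.default_mst_scenario,
        "parb": synthetic.default_parb_emsa_scenario,
    }
    out: dict[str, dict] = {}
    for i, name in enumerate(wanted):
        if name not in makers:
            raise ConfigError(f"unknown isotherm scenario {name!r}")
        overrides = {}
        if "noise_sd" in cfg:
            overrides["noise_sd"] = float(cfg["noise_sd"])
        scen = makers[name](seed=stage_seed(seed, f"isotherm:{name}"), **overrides)
        iso = synthetic.simulate_isotherm(scen)
        synthetic.write_isotherm_csv(iso, outdir / f"isotherm_{name}.csv")
        if scen.model_kind == "hill":
            fit = binding.fit_hill(iso)
        else:
            fit = binding.fit_depletion(iso)
        out[name] = {
            "model": fit.model_kind,
            "kd_app_nM": fit.kd_app_nM,
            "hill_h": fit.hill_h,
            "kd_true_nM": scen.kd_true,
        }
    if "emsa" in out and "parb" in out:
        out["fold_stimulation"] = binding.fold_stimulation(
            out["emsa"]["kd_app_nM"], out["parb"]["kd_app_nM"]
        )
    (outdir / "isotherm_fits.json").write_text(json.dumps(out, indent=2) + "\n")
    return out


def _run_geometry(cfg: dict, seed: int, outdir: Path, motifs_result: dict | None) -> dict:
    sep = cfg.get("center_sep_bp")
    if sep is None:
        sep = (motifs_result or {}).get("perfect_center_distance") or 34
    model = geometry.HelixModel(
        rise_nm=float(cfg.get("rise_nm", 0.34)),
        bp_per_turn=float(cfg.get("bp_per_turn", 10.5)),
    )
    span = tuple(cfg.get("span_nm", (10.0, 11.0)))
    grid = np.arange(
        0.0, float(cfg.get("bend_max_deg", 5.0)) + 1e-9,
        float(cfg.get("bend_step_deg", 0.25)),
    )
    scan = geometry.scan_bend_for_span(sep, span, model, grid)
    scan.to_json(outdir / "bend_scan.json")
    scan.table.to_csv(outdir / "bend_scan.csv", index=False)
    offset, same = geometry.face_offset(sep, model.bp_per_turn)
    best_chord = None
    if scan.best_bend_deg is not None:
        best_chord = geometry.chord_distance(
            sep, geometry.HelixModel(model.rise_nm, model.bp_per_turn, scan.best_bend_deg)
        )
    return {
        "center_sep_bp": sep,
        "contour_nm": sep * model.rise_nm,
        "face_offset_deg": offset,
        "same_face": same,
        "feasible_bends_deg": scan.feasible_bends_deg,
        "best_bend_deg": scan.best_bend_deg,
        "best_chord_nm": best_chord,
    }


def _run_flexibility(cfg: dict, seed: int, outdir: Path) -> dict:
    overrides = dict(cfg)
    if "loop_interval" in overrides:
        overrides["loop_interval"] = tuple(overrides["loop_interval"])
    scen = synthetic.wing_marker_trajectory_scenario(seed=seed, **overrides)
    traj = synthetic.simulate_trajectory(scen)
    synthetic.write_trajectory_csv(traj, outdir / "trajectory.csv")
    profile = flexibility.fluctuation_profile(traj)
    flexibility.write_profile_csv(profile, outdir / "fluctuation_profile.csv")
    regions = flexibility.flexible_regions(profile)
    rms = flexibility.rmsd_series(traj)
    result: dict = {
        "n_frames": traj.n_frames,
        "n_residues": traj.n_atoms,
        "rmsd_final_A": float(rms[-1]),
        "regions": [
            {
                "start": r.start_residue,
                "end": r.end_residue,
                "peak_residue": r.peak_residue,
                "peak_bfactor_A2": r.peak_bfactor,
            }
            for r in regions
        ],
    }
    if scen.marker_residue is not None:
        lo, hi = scen.loop_interval
        core = [r for r in range(1, scen.n_residues + 1) if not lo <= r <= hi]
        result["marker_residue"] = scen.marker_residue
        result["marker_displacement_A"] = flexibility.displacement(
            traj, scen.marker_residue, core
        )
    (outdir / "flexible_regions.json").write_text(
        json.dumps(result["regions"], indent=2) + "\n"
    )
    return result


def _run_thermal(cfg: dict, seed: int, outdir: Path) -> dict:
    conditions = cfg.get("conditions", synthetic.default_melt_conditions())
    window = float(cfg.get("smooth_window_C", 1.5))
    results = []
    for i, (label, tm_true) in enumerate(conditions.items()):
        scen = synthetic.MeltScenario(
            tm_true=float(tm_true),
            dH_vant_hoff=float(cfg.get("dH_vant_hoff", 300.0)),
            noise_sd=float(cfg.get("noise_sd", 0.0)),
            seed=stage_seed(seed, f"melt:{label}"),
            label=label,
        )
        curve = synthetic.simulate_melt_curve(scen)
        thermal.write_melt_csv(curve, outdir / f"melt_{label}.csv")
        results.append(thermal.extract_tm(curve, smooth_window_C=window))
    table = thermal.tm_table(results)
    table.to_csv(outdir / "tm_table.tsv", sep="\t", index=False)
    return {
        "conditions": {
            r.label: {"tm_C": round(r.tm, 2)} for r in results
        },
        "delta_vs_first_C": {
            row["condition"]: row["delta_tm_C"] for _, row in table.iterrows()
        },
    }


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Execute the requested stages in dependency order and write a report.

    Identical config + seed give identical reports.  A stage failure raises
    :class:`StageError` naming the stage; outputs of completed stages are
    retained in the output directory.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    requested = config.stages if config.stages else {name: {} for name in STAGES}
    results: dict[str, dict] = {}
    skipped = [name for name in STAGES if name not in requested]
    motifs_result: dict | None = None
    for name in STAGES:
        if name not in requested:
            continue
        cfg = requested[name] or {}
        sseed = stage_seed(config.seed, name) if config.seed is not None else 0
        log.info("[%s] running (substream seed %d)", name, sseed)
        try:
            if name == "motifs":
                motifs_result = _run_motifs(cfg, sseed, outdir)
                results[name] = motifs_result
            elif name == "spr":
                results[name] = _run_spr(cfg, sseed, outdir)
            elif name == "isotherms":
                results[name] = _run_isotherms(cfg, sseed, outdir)
            elif name == "geometry":
                results[name] = _run_geometry(cfg, sseed, outdir, motifs_result)
            elif name == "flexibility":
                results[name] = _run_flexibility(cfg, sseed, outdir)
            elif name == "thermal":
                results[name] = _run_thermal(cfg, sseed, outdir)
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise StageError(name, exc) from exc
    report = PipelineReport(
        stages=results,
        skipped=skipped,
        seed=config.seed,
        config_hash=config.config_hash,
        version=__version__,
    )
    (outdir / "report.json").write_text(
        json.dumps(report.to_dict(), indent=2, default=_json_default) + "\n"
    )
    return report


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
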