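"""Pipeline orchestration: run the analysis stages from a single config.

Stages run in dependency order — simulate, tht, ss, topology, sasa,
agreement — each writing deterministic TSV/JSON outputs into the run
directory. All randomness flows from the single top-level seed via
stage-name-hashed derived seeds, so an identical config reproduces every
numeric output byte-for-byte (wall times live only in run_report.json).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from hashlib import sha256
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import chemshift_ss, io_formats, probe_topology, sasa_orientation
from . import synthetic_data as synth
from . import tht_kinetics as tht

__all__ = ["RunConfig", "run_pipeline", "PipelineError", "STAGES"]

log = logging.getLogger("memtrap")

STAGES = ("simulate", "tht", "ss", "topology", "sasa", "agreement")

_INPUT_KEYS = {
    "plate", "plate_meta", "shifts", "intensity_ref", "intensity_nd",
    "intensity_gd", "intensity_dsa", "structure_complex", "structure_alone",
    "structure_map",
}


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Validated pipeline configuration.

    ``stages`` toggles each stage; ``inputs`` holds file paths (optional
    when the simulate stage provides them); ``params`` holds per-stage
    parameter blocks forwarded to the stage functions. Unknown keys are
    rejected everywhere.
    """

    seed: int
    outdir: Path
    stages: dict[str, bool] = field(default_factory=dict)
    inputs: dict[str, str] = field(default_factory=dict)
    params: dict[str, dict] = field(default_factory=dict)
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise PipelineError(f"unknown stages in config: {sorted(unknown)}")
        unknown = set(self.inputs) - _INPUT_KEYS
        if unknown:
            raise PipelineError(f"unknown input keys: {sorted(unknown)}")
        unknown = set(self.params) - set(STAGES)
        if unknown:
            raise PipelineError(f"unknown parameter blocks: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {"seed", "outdir", "stages", "inputs", "params", "log_level"}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        if "seed" not in raw or "outdir" not in raw:
            raise PipelineError("config must provide 'seed' and 'outdir'")
        return cls(
            seed=int(raw["seed"]),
            outdir=raw["outdir"],
            stages={k: bool(v) for k, v in (raw.get("stages") or {}).items()},
            inputs=dict(raw.get("inputs") or {}),
            params={k: dict(v or {}) for k, v in (raw.get("params") or {}).items()},
            log_level=raw.get("log_level", "INFO"),
        )

    def enabled(self, stage: str) -> bool:
        return bool(self.stages.get(stage, False))

    def params_hash(self, stage: str) -> str:
        blob = json.dumps(
            {"seed": self.seed, "params": self.params.get(stage, {})},
            sort_keys=True, default=str,
        )
        return sha256(blob.encode()).hexdigest()[:12]


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")


# ---------------------------------------------------------------------------
# Stage implementations (also the surface the analysis scripts drive)
# ---------------------------------------------------------------------------

def stage_simulate(seed: int, outdir: Path, **overrides) -> dict[str, str]:
    """Generate all four synthetic input kinds plus truth tables."""
    outdir.mkdir(parents=True, exist_ok=True)
    spec_kwargs = {}
    for block, cls in (("tht", synth.ThtSpec), ("shifts", synth.ShiftSpec),
                       ("probes", synth.ProbeSpec),
                       ("geometry", synth.GeometrySpec)):
        if block in overrides:
            spec_kwargs[block] = cls(**overrides.pop(block))
    if overrides:
        raise PipelineError(f"unknown simulate parameters: {sorted(overrides)}")
    spec = synth.SimSpec(seed=seed, **spec_kwargs)

    plate, tht_truth = synth.gen_tht_plate(spec)
    io_formats.write_plate_csv(plate, outdir / "plate.csv", outdir / "plate_meta.yaml")
    _write_tsv(tht_truth, outdir / "truth_tht.tsv")

    table, ss_truth = synth.gen_shift_table(spec)
    io_formats.write_shift_table(table, outdir / "shifts.tsv")
    _write_json({"ss_string": ss_truth}, outdir / "truth_ss.json")

    iref, ind, igd, idsa, topo_truth = synth.gen_probe_tables(spec)
    for name, tab in (("ref", iref), ("nd", ind), ("gd", igd), ("dsa", idsa)):
        io_formats.write_intensity_table(tab, outdir / f"intensity_{name}.tsv")
    _write_json({str(k): v for k, v in topo_truth.items()},
                outdir / "truth_topology.json")

    alone, complex_, contacts = synth.gen_membrane_complex(spec)
    io_formats.write_pdb(alone, outdir / "peptide_alone.pdb")
    io_formats.write_pdb(complex_, outdir / "peptide_membrane.pdb")
    _write_json({"contacts": sorted(contacts)}, outdir / "truth_contacts.json")

    _write_json(spec.to_dict(), outdir / "sim_spec.json")
    return {
        "plate": str(outdir / "plate.csv"),
        "plate_meta": str(outdir / "plate_meta.yaml"),
        "shifts": str(outdir / "shifts.tsv"),
        "intensity_ref": str(outdir / "intensity_ref.tsv"),
        "intensity_nd": str(outdir / "intensity_nd.tsv"),
        "intensity_gd": str(outdir / "intensity_gd.tsv"),
        "intensity_dsa": str(outdir / "intensity_dsa.tsv"),
        "structure_alone": str(outdir / "peptide_alone.pdb"),
        "structure_complex": str(outdir / "peptide_membrane.pdb"),
    }


def stage_tht(plate: str, plate_meta: str, outdir: Path,
              background: float = 0.0) -> dict:
    """Fit every well, extract lag times, summarize per condition."""
    outdir.mkdir(parents=True, exist_ok=True)
    run = io_formats.read_plate_csv(plate, plate_meta)
    traces = tht.normalize_plate(run, background=background)
    fit_rows = []
    results = []
    for well in sorted(traces):
        trace = traces[well]
        fit, lag = tht.analyze_trace(trace)
        fit_rows.append(
            {
                "well": well,
                "replicate_group": trace.condition.get("replicate_group"),
                "censored": lag.censored,
                "F0": fit.F0 if fit else np.nan,
                "Finf": fit.Finf if fit else np.nan,
                "k_per_min": fit.k if fit else np.nan,
                "t50_min": fit.t50 if fit else np.nan,
                "rmse": fit.rmse if fit else np.nan,
                "converged": fit.converged if fit else False,
                "t_lag_min": lag.t_lag if lag.t_lag is not None else np.nan,
                "lag_lower_bound_min": lag.lower_bound
                if lag.lower_bound is not None else np.nan,
            }
        )
        results.append((lag, trace.condition))
    fits = pd.DataFrame(fit_rows)
    summary = tht.summarize_conditions(results)
    _write_tsv(fits, outdir / "tht_fits.tsv")
    _write_tsv(summary, outdir / "tht_summary.tsv")
    return {
        "n_wells": len(fits),
        "n_censored": int(fits["censored"].sum()),
        "outputs": ["tht_fits.tsv", "tht_summary.tsv"],
        "normalization_scope": "per-well (plate-referenced censoring)",
    }


def stage_ss(shifts: str, outdir: Path, sequence: str | None = None,
             rc_table: str = "wishart95", window: int = 5,
             strand_thr: float = -0.7, helix_thr: float = 0.7,
             use: str = "dCaCb", min_strand_len: int = 3,
             min_helix_len: int = 4, bridge_single_gap: bool = True,
             boundary_min_fraction: float = 0.5) -> dict:
    """Secondary shifts, propensity score, segment calls."""
    outdir.mkdir(parents=True, exist_ok=True)
    table = io_formats.read_shift_table(shifts, sequence=sequence)
    profile = chemshift_ss.secondary_shifts(table, rc_table)
    profile = chemshift_ss.ssp_score(profile, window=window)
    call = chemshift_ss.call_segments(
        profile, strand_thr=strand_thr, helix_thr=helix_thr, use=use,
        min_strand_len=min_strand_len, min_helix_len=min_helix_len,
        bridge_single_gap=bridge_single_gap,
        boundary_min_fraction=boundary_min_fraction,
    )
    out = profile.data.reset_index()
    out["label"] = [call.labels[int(i)] for i in out["residue_index"]]
    _write_tsv(out, outdir / "ss_profile.tsv")
    _write_json(
        {
            "segments": [
                {"start": s.start, "end": s.end, "type": s.kind}
                for s in call.segments
            ],
            "provenance": profile.provenance,
        },
        outdir / "ss_segments.json",
    )
    return {
        "n_assigned": int(out["assigned"].sum()),
        "segments": [(s.start, s.end, s.kind) for s in call.segments],
        "outputs": ["ss_profile.tsv", "ss_segments.json"],
    }


def stage_topology(intensity_ref: str, intensity_nd: str, intensity_gd: str,
                   intensity_dsa: str, outdir: Path,
                   sequence: str = synth.HIAPP_SEQUENCE,
                   threshold_rule: str = "mean",
                   structure_map: str | None = None) -> dict:
    """Per-probe reduction profiles and the consensus topology call."""
    outdir.mkdir(parents=True, exist_ok=True)
    ref = io_formats.read_intensity_table(intensity_ref)
    profiles = {}
    for name, path in (("nd", intensity_nd), ("gd", intensity_gd),
                       ("dsa", intensity_dsa)):
        probe = io_formats.read_intensity_table(path)
        prof = probe_topology.reduction_profile(ref, probe, threshold_rule)
        profiles[name] = prof
        rows = [
            {
                "residue_index": ri,
                "reduction": prof.reductions[ri],
                "above_average": ri in prof.above_average,
            }
            for ri in sorted(prof.reductions)
        ]
        _write_tsv(pd.DataFrame(rows), outdir / f"reduction_{name}.tsv")
    call = probe_topology.consensus_topology(
        profiles["nd"], profiles["gd"], profiles["dsa"], sequence
    )
    rows = [
        {
            "residue_index": ri,
            "aa": sequence[ri - 1],
            "label": call.labels[ri],
            "nd_flag": call.evidence[ri]["ND"],
            "gd_flag": call.evidence[ri]["Gd"],
            "dsa_flag": call.evidence[ri]["DSA"],
        }
        for ri in sorted(call.labels)
    ]
    _write_tsv(pd.DataFrame(rows), outdir / "topology.tsv")
    _write_json(
        {
            "labels": {str(k): v for k, v in call.labels.items()},
            "rule": call.rule,
            "threshold_rule": threshold_rule,
            "mean_reductions": {
                name: profiles[name].mean_reduction for name in profiles
            },
        },
        outdir / "topology.json",
    )
    outputs = ["reduction_nd.tsv", "reduction_gd.tsv", "reduction_dsa.tsv",
               "topology.tsv", "topology.json"]
    if structure_map:
        structure = io_formats.read_pdb(
            structure_map, group_rules={"A": "peptide", "B": "membrane"},
            radius_set="martini-cg",
        )
        probe_topology.map_to_structure(
            call, structure, outdir / "topology_mapped.pdb",
            outdir / "topology_legend.tsv",
        )
        outputs += ["topology_mapped.pdb", "topology_legend.tsv"]
    return {
        "membrane": sorted(call.residues("membrane")),
        "solvent": sorted(call.residues("solvent")),
        "ambiguous": sorted(call.residues("ambiguous")),
        "outputs": outputs,
    }


def stage_sasa(structure_complex: str, structure_alone: str, outdir: Path,
               probe_radius: float = 0.0, n_points: int = 960,
               radius_augment: float = 0.21, radius_set: str = "martini-cg",
               min_area: float = 0.10,
               group_rules: dict | None = None) -> dict:
    """Per-residue SASA of the peptide alone and in complex; lipid split."""
    outdir.mkdir(parents=True, exist_ok=True)
    rules = group_rules or {"A": "peptide", "B": "membrane"}
    kwargs = dict(probe_radius=probe_radius, n_points=n_points,
                  radius_augment=radius_augment, radius_set_name=radius_set)

    def averaged(path: str) -> sasa_orientation.SASAProfile:
        models = io_formats.read_pdb_models(path, rules, radius_set)
        profs = [
            sasa_orientation.sasa(m, subset=["peptide"], **kwargs)
            for m in models
        ]
        return profs[0] if len(profs) == 1 else sasa_orientation.mean_sasa(profs)

    alone = averaged(structure_alone)
    complex_ = averaged(structure_complex)
    split = sasa_orientation.accessibility_split(alone, complex_, min_area=min_area)
    rows = [
        {
            "residue_index": ri,
            "sasa_alone_nm2": alone.residue_areas[ri],
            "sasa_complex_nm2": complex_.residue_areas[ri],
            "solvent_area_nm2": split.solvent_area[ri],
            "lipid_area_nm2": split.lipid_area[ri],
            "preference": split.preference[ri],
        }
        for ri in sorted(split.preference)
    ]
    _write_tsv(pd.DataFrame(rows), outdir / "sasa_split.tsv")
    _write_json(
        {"params": alone.params, "min_area": min_area,
         "lipid_preferring": sorted(split.residues("lipid"))},
        outdir / "sasa_params.json",
    )
    return {
        "lipid_preferring": sorted(split.residues("lipid")),
        "outputs": ["sasa_split.tsv", "sasa_params.json"],
    }


def stage_agreement(outdir: Path, topology_dir: Path, sasa_dir: Path) -> dict:
    """Contingency between the NMR membrane set and the SASA lipid set."""
    outdir.mkdir(parents=True, exist_ok=True)
    topo = json.loads((topology_dir / "topology.json").read_text())
    split_df = pd.read_csv(sasa_dir / "sasa_split.tsv", sep="\t")
    support = set(split_df["residue_index"].astype(int))
    nmr_set = {
        int(ri) for ri, lab in topo["labels"].items()
        if lab == "membrane" and int(ri) in support
    }
    sasa_set = {
        int(r.residue_index) for r in split_df.itertuples()
        if r.preference == "lipid"
    }
    both = nmr_set & sasa_set
    denom = min(len(nmr_set), len(sasa_set))
    overlap = (len(both) / denom) if (nmr_set and denom) else None
    report = {
        "both": sorted(both),
        "nmr_only": sorted(nmr_set - sasa_set),
        "sasa_only": sorted(sasa_set - nmr_set),
        "neither": sorted(support - nmr_set - sasa_set),
        "overlap_coefficient": overlap,
        "overlap_undefined": not nmr_set,
    }
    _write_json(report, outdir / "agreement.json")
    return {
        "overlap_coefficient": overlap,
        "counts": {k: len(report[k]) for k in ("both", "nmr_only", "sasa_only",
                                               "neither")},
        "outputs": ["agreement.json"],
    }


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order; return the report.

    The report (also written to ``run_report.json``) lists per-stage
    outputs, parameters hash, warnings and wall time. Any stage error
    aborts with a partial-results manifest and re-raises.
    """
    logging.basicConfig(level=config.log_level)
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    inputs = dict(config.inputs)

    def need(stage: str, *keys: str) -> None:
        missing = [k for k in keys if k not in inputs]
        if missing:
            raise PipelineError(
                f"stage '{stage}' needs inputs {missing}; provide them in "
                "config.inputs or enable the simulate stage"
            )

    if config.enabled("agreement") and not (
        config.enabled("topology") and config.enabled("sasa")
    ):
        raise PipelineError(
            "stage 'agreement' requires stages 'topology' and 'sasa' in the "
            "same run"
        )

    report: dict = {"seed": config.seed, "stages": {}}
    t_all = time.perf_counter()
    for stage in STAGES:
        if not config.enabled(stage):
            continue
        params = dict(config.params.get(stage, {}))
        t0 = time.perf_counter()
        try:
            if stage == "simulate":
                produced = stage_simulate(config.seed, outdir / "synthetic",
                                          **params)
                for key, path in produced.items():
                    inputs.setdefault(key, path)
                result = {"outputs": sorted(Path(p).name for p in produced.values())}
            elif stage == "tht":
                need(stage, "plate", "plate_meta")
                result = stage_tht(inputs["plate"], inputs["plate_meta"],
                                   outdir / "tht", **params)
            elif stage == "ss":
                need(stage, "shifts")
                result = stage_ss(inputs["shifts"], outdir / "ss", **params)
            elif stage == "topology":
                need(stage, "intensity_ref", "intensity_nd", "intensity_gd",
                     "intensity_dsa")
                result = stage_topology(
                    inputs["intensity_ref"], inputs["intensity_nd"],
                    inputs["intensity_gd"], inputs["intensity_dsa"],
                    outdir / "topology",
                    structure_map=inputs.get("structure_map"), **params,
                )
            elif stage == "sasa":
                need(stage, "structure_complex", "structure_alone")
                result = stage_sasa(inputs["structure_complex"],
                                    inputs["structure_alone"],
                                    outdir / "sasa", **params)
            elif stage == "agreement":
                result = stage_agreement(outdir / "agreement",
                                         outdir / "topology", outdir / "sasa")
        except Exception as exc:
            report["stages"][stage] = {"status": "error", "error": str(exc)}
            report["status"] = "error"
            _write_json(report, outdir / "run_report.json")
            raise
        wall = time.perf_counter() - t0
        log.info("stage %s done in %.2fs params_hash=%s", stage, wall,
                 config.params_hash(stage))
        report["stages"][stage] = {
            "status": "ok",
            "params": params,
            "params_hash": config.params_hash(stage),
            "wall_time_s": round(wall, 3),
            **result,
        }
    report["status"] = "ok"
    report["total_wall_time_s"] = round(time.perf_counter() - t_all, 3)
    _write_json(report, outdir / "run_report.json")
    return report
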