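"""End-to-end orchestration of the synthetic self-assembly analysis.

A single :class:`RunConfig` drives up to five stages —

    simulate -> fcs-fit -> build-fibril -> rdf -> pmf

— writing per-stage artifacts plus a machine-readable ``summary.json``
(population fractions, modal diffusivities, RDF peaks, dissociation
energies and their ratio, and a manifest with a content hash per output
file) and a human-readable ``report.txt``.  Reruns with the same seed
reproduce the manifest hashes bit for bit.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import fcs, fibril, io, mem, metrics, pmf, synthetic

__all__ = ["RunConfig", "ConfigError", "run_pipeline", "default_config", "DEMO_CONFIG"]

logger = logging.getLogger("oligofib")


class ConfigError(ValueError):
    """Raised for unknown keys or missing inputs in a run configuration."""


#: Full default configuration; every knob the pipeline understands appears
#: here, so unknown user keys can be rejected by name.
_DEFAULTS: dict = {
    "seed": 0,
    "output_dir": "oligofib_run",
    "log_level": "INFO",
    "stages": ["simulate", "fcs-fit", "build-fibril", "rdf", "pmf"],
    "fcs": {
        "presets": ["slp1_like", "slp3_like"],
        "gamma": 6.0,
        "grid_n": 100,
        "chi2_target": None,
        "cutoff_d": 150.0,
        "focal_w_xy": 0.3,
        "curve_files": None,
    },
    "fibril": {
        "n_strands": 36,
        "n_sheets": 2,
        "intra_sheet_spacing": 5.0,
        "inter_sheet_spacing": 10.0,
        "antiparallel": True,
        "interdigitated": False,
        "twist_per_strand": 0.0,
        "residue_count": 7,
    },
    "rdf": {
        "bin_width": 0.1,
        "r_max": 20.0,
        "level": "strand",  # "strand" centroids or "atom" backbone
    },
    "pmf": {
        "landscapes": ["fibril_like", "oligomer_like"],
        "n_traces": 12,
        "rate": 0.002,
        "dt": 0.02,
        "temperature": 300.0,
        "r_points": 200,
        "trace_files": None,
    },
}

#: The all-synthetic demo configuration (small trace counts keep it fast).
DEMO_CONFIG = copy.deepcopy(_DEFAULTS)


def default_config() -> dict:
    return copy.deepcopy(_DEFAULTS)


def _merge(defaults, user, path=""):
    out = copy.deepcopy(defaults)
    for key, value in user.items():
        if key not in defaults:
            raise ConfigError(f"unknown configuration key: {path}{key}")
        if isinstance(defaults[key], dict) and isinstance(value, dict):
            out[key] = _merge(defaults[key], value, path=f"{path}{key}.")
        else:
            out[key] = value
    return out


@dataclass(frozen=True)
class RunConfig:
    """Validated pipeline configuration (unknown keys rejected by name)."""

    settings: dict = field(default_factory=default_config)

    @classmethod
    def from_dict(cls, user: dict) -> "RunConfig":
        return cls(settings=_merge(_DEFAULTS, user))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        user = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(user, dict):
            raise ConfigError("configuration file must hold a mapping")
        return cls.from_dict(user)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.settings, sort_keys=True)

    def __getitem__(self, key):
        return self.settings[key]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig | dict | None = None) -> dict:
    """Execute the configured stages and return the summary dictionary.

    Stage failures are logged and downstream dependents are skipped; the
    summary's ``failed_stages`` entry records them.  All artifacts,
    ``summary.json`` and ``report.txt`` are written under
    ``config["output_dir"]``.
    """
    if config is None:
        config = RunConfig()
    elif isinstance(config, dict):
        config = RunConfig.from_dict(config)
    cfg = config.settings
    logging.basicConfig(
        level=getattr(logging, str(cfg["log_level"]).upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
    out_dir = Path(cfg["output_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    stages = list(cfg["stages"])
    logger.info("pipeline start: stages=%s seed=%d out=%s", stages, seed, out_dir)
    logger.info("resolved configuration:\n%s", config.to_yaml())

    summary: dict = {"seed": seed, "stages": {}, "failed_stages": []}
    artifacts: list[Path] = []
    state: dict = {}

    def run_stage(name, func, requires=()):
        if name not in stages:
            return
        missing = [r for r in requires if r in summary["failed_stages"]]
        if missing:
            logger.warning("skipping stage %s (failed dependencies: %s)", name, missing)
            summary["failed_stages"].append(name)
            return
        t0 = time.perf_counter()
        try:
            summary["stages"][name] = func()
            logger.info("stage %s done in %.2f s", name, time.perf_counter() - t0)
        except Exception:
            logger.exception("stage %s failed", name)
            summary["failed_stages"].append(name)

    def stage_simulate():
        block = {"curves": {}, "traces": {}}
        for i, preset in enumerate(cfg["fcs"]["presets"]):
            curve = synthetic.generate_fcs_curve(preset, seed=seed + i)
            path = out_dir / f"curve_{preset}.csv"
            io.write_correlation_csv(path, curve, comment=f"synthetic preset {preset}")
            artifacts.append(path)
            block["curves"][preset] = path.name
        for j, land in enumerate(cfg["pmf"]["landscapes"]):
            traces = synthetic.generate_pull_traces(
                land,
                n=int(cfg["pmf"]["n_traces"]),
                rate=float(cfg["pmf"]["rate"]),
                dt=float(cfg["pmf"]["dt"]),
                seed=seed + 1000 + j,
            )
            names = []
            for m, tr in enumerate(traces):
                path = out_dir / f"pull_{land}_{m:03d}.xvg"
                io.write_pull_xvg(path, tr, comment=f"synthetic landscape {land}")
                artifacts.append(path)
                names.append(path.name)
            block["traces"][land] = names
        return block

    def stage_fcs_fit():
        focal = fcs.FocalVolume(float(cfg["fcs"]["focal_w_xy"]))
        grid = mem.MemGrid.default(n=int(cfg["fcs"]["grid_n"]))
        chi2_target = cfg["fcs"]["chi2_target"]
        block = {}
        sources: dict[str, Path] = {}
        if cfg["fcs"]["curve_files"]:
            for f in cfg["fcs"]["curve_files"]:
                p = Path(f)
                if not p.exists():
                    raise ConfigError(f"missing FCS input file: {p}")
                sources[p.stem] = p
        else:
            for preset in cfg["fcs"]["presets"]:
                p = out_dir / f"curve_{preset}.csv"
                if not p.exists():
                    raise ConfigError(f"missing FCS input file: {p} (run the simulate stage?)")
                sources[preset] = p
        for label, path in sources.items():
            curve = io.read_correlation_csv(path)
            sol = mem.mem_fit(
                curve,
                grid,
                gamma=float(cfg["fcs"]["gamma"]),
                chi2_target=None if chi2_target is None else float(chi2_target),
            )
            pop = mem.split_populations(
                sol, focal, cutoff_d=float(cfg["fcs"]["cutoff_d"]), force=True
            )
            dist_path = out_dir / f"distribution_{label}.csv"
            io.write_distribution_csv(dist_path, sol, focal)
            pop_path = out_dir / f"population_{label}.json"
            io.write_population_json(
                pop_path, pop, extra={"entropy": sol.entropy, "chi_squared": sol.chi_squared}
            )
            artifacts.extend([dist_path, pop_path])
            block[label] = {
                "monomer_fraction": pop.monomer_fraction,
                "oligomer_fraction": pop.oligomer_fraction,
                "modal_d_monomer_um2s": pop.modal_d_monomer,
                "modal_d_oligomer_um2s": pop.modal_d_oligomer,
                "entropy": sol.entropy,
                "chi_squared": sol.chi_squared,
                "converged": sol.converged,
            }
        return block

    def stage_build_fibril():
        fib_cfg = cfg["fibril"]
        spec = fibril.LatticeSpec(
            n_strands=int(fib_cfg["n_strands"]),
            n_sheets=int(fib_cfg["n_sheets"]),
            intra_sheet_spacing=float(fib_cfg["intra_sheet_spacing"]),
            inter_sheet_spacing=float(fib_cfg["inter_sheet_spacing"]),
            antiparallel=bool(fib_cfg["antiparallel"]),
            interdigitated=bool(fib_cfg["interdigitated"]),
            twist_per_strand=float(fib_cfg["twist_per_strand"]),
        )
        lattice = fibril.build_fibril_lattice(
            spec, fibril.StrandGeometry(residue_count=int(fib_cfg["residue_count"]))
        )
        state["lattice"] = lattice
        path = out_dir / "fibril.pdb"
        io.lattice_to_pdb(path, lattice)
        artifacts.append(path)
        contacts = fibril.intermolecular_contacts(lattice)
        alignment = fibril.classify_alignment(contacts)
        return {
            "n_strands": lattice.n_strands,
            "n_atoms": int(lattice.coords.shape[0]),
            "alignment": alignment,
            "n_contacts": len(contacts.contacts),
            "pdb": path.name,
        }

    def stage_rdf():
        lattice = state.get("lattice")
        if lattice is None:
            pdb_path = out_dir / "fibril.pdb"
            if not pdb_path.exists():
                raise ConfigError(f"missing fibril coordinates: {pdb_path}")
            coords, chains, _, names = io.read_pdb_coordinates(pdb_path)
            bb = np.isin(names, fibril.BACKBONE_ATOMS)
            if cfg["rdf"]["level"] == "strand":
                pts = np.array(
                    [coords[bb & (chains == c)].mean(axis=0) for c in np.unique(chains)]
                )
                groups = np.unique(chains)
            else:
                pts, groups = coords[bb], chains[bb]
        elif cfg["rdf"]["level"] == "strand":
            pts, groups, _ = lattice.strand_centroids()
        else:
            bb = lattice.backbone_mask()
            pts, groups = lattice.coords[bb], lattice.strand_ids[bb]
        rdf = metrics.radial_distribution(
            pts,
            groups,
            bin_width=float(cfg["rdf"]["bin_width"]),
            r_max=float(cfg["rdf"]["r_max"]),
        )
        rdf_path = out_dir / "rdf.csv"
        import pandas as pd

        pd.DataFrame({"r_A": rdf.bin_centers, "g": rdf.g_values}).to_csv(
            rdf_path, index=False, float_format="%.10g"
        )
        peaks_path = out_dir / "rdf_peaks.json"
        peaks_path.write_text(json.dumps({"peaks_A": list(map(float, rdf.peaks))}, indent=2) + "\n")
        artifacts.extend([rdf_path, peaks_path])
        return {"peaks_A": list(map(float, rdf.peaks[:6])), "n_pairs": rdf.n_pairs}

    def stage_pmf():
        pmf_cfg = cfg["pmf"]
        block = {}
        energies = {}
        for land in pmf_cfg["landscapes"]:
            if pmf_cfg["trace_files"]:
                paths = [Path(f) for f in pmf_cfg["trace_files"].get(land, [])]
            else:
                paths = sorted(out_dir.glob(f"pull_{land}_*.xvg"))
            if not paths:
                raise ConfigError(f"no pulling traces found for landscape {land}")
            traces = [io.read_pull_xvg(p) for p in paths]
            # span of the spring-reference coordinate, common to all traces
            r_max = min(
                tr.position[0] + tr.pull_rate * (tr.time[-1] - tr.time[0]) for tr in traces
            )
            r_grid = np.linspace(0.0, r_max, int(pmf_cfg["r_points"]))
            works = [pmf.accumulate_work(tr, r_grid) for tr in traces]
            profile = pmf.jarzynski_pmf(works, temperature=float(pmf_cfg["temperature"]))
            dgd = pmf.dissociation_energy(profile)
            pmf_path = out_dir / f"pmf_{land}.csv"
            io.write_pmf_csv(pmf_path, profile)
            artifacts.append(pmf_path)
            energies[land] = dgd
            block[land] = {"dGd_kJmol": dgd, "n_trajectories": profile.n_trajectories}
        lands = list(pmf_cfg["landscapes"])
        if len(lands) == 2:
            ratio = pmf.stability_ratio(energies[lands[0]], energies[lands[1]])
            block["stability_ratio"] = ratio
        summary_path = out_dir / "pmf_summary.json"
        summary_path.write_text(json.dumps(io._jsonify(block), indent=2, sort_keys=True) + "\n")
        artifacts.append(summary_path)
        return block

    run_stage("simulate", stage_simulate)
    run_stage("fcs-fit", stage_fcs_fit, requires=["simulate"])
    run_stage("build-fibril", stage_build_fibril)
    run_stage("rdf", stage_rdf, requires=["build-fibril"])
    run_stage("pmf", stage_pmf, requires=["simulate"])

    summary["manifest"] = {p.name: _sha256(p) for p in sorted(set(artifacts))}
    summary_path = out_dir / "summary.json"
    summary_path.write_text(json.dumps(io._jsonify(summary), indent=2, sort_keys=True) + "\n")
    (out_dir / "report.txt").write_text(_render_report(summary))
    logger.info("pipeline finished; summary at %s", summary_path)
    return summary


def _render_report(summary: dict) -> str:
    lines = [
        "oligofib pipeline report",
        "========================",
        f"seed: {summary['seed']}",
        "",
    ]
    for stage, block in summary["stages"].items():
        lines.append(f"[{stage}]")
        lines.append(json.dumps(io._jsonify(block), indent=2, sort_keys=True))
        lines.append("")
    if summary["failed_stages"]:
        lines.append(f"FAILED stages: {summary['failed_stages']}")
    lines.append(f"artifacts: {len(summary['manifest'])} files (sha256 in summary.json)")
    return "\n".join(lines) + "\n"
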