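"""Readers and writers for the pipeline's on-disk formats.

* Correlation CSV: comment lines start with ``#``; header ``lag_s,g``
  with optional ``sd_g`` column.
* Distribution CSV: ``tau_s,alpha,rho,D_um2s`` per MEM grid point.
* XVG-style pull traces: whitespace tables with ``@``/``#`` comment lines
  and columns time (ps), position (nm), force (kJ/mol/nm).
* PMF CSV: ``r_nm,dG_kJmol``.
* PDB: one strand per chain, written/read with biotite.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import biotite.structure as struc
import biotite.structure.io.pdb as pdb

from .fcs import AutocorrelationCurve, FocalVolume
from .mem import MemSolution, PopulationSummary
from .pmf import PmfProfile, PullTrace
from .fibril import FibrilLattice

__all__ = [
    "read_correlation_csv",
    "write_correlation_csv",
    "write_distribution_csv",
    "write_population_json",
    "read_pull_xvg",
    "write_pull_xvg",
    "write_pmf_csv",
    "lattice_to_pdb",
    "read_pdb_coordinates",
]

# 36 chains: A-Z then 0-9
_CHAIN_IDS = [chr(c) for c in range(ord("A"), ord("Z") + 1)] + [str(d) for d in range(10)]


def read_correlation_csv(path) -> AutocorrelationCurve:
    df = pd.read_csv(path, comment="#")
    required = {"lag_s", "g"}
    if not required <= set(df.columns):
        raise ValueError(f"correlation CSV needs columns {sorted(required)}, got {list(df.columns)}")
    weights = df["sd_g"].to_numpy() if "sd_g" in df.columns else None
    return AutocorrelationCurve(
        lags=df["lag_s"].to_numpy(), values=df["g"].to_numpy(), weights=weights
    )


def write_correlation_csv(path, curve: AutocorrelationCurve, comment: str | None = None):
    path = Path(path)
    df = pd.DataFrame({"lag_s": curve.lags, "g": curve.values})
    if curve.weights is not None:
        df["sd_g"] = curve.weights
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        df.to_csv(fh, index=False, float_format="%.10g")


def write_distribution_csv(path, sol: MemSolution, focal: FocalVolume):
    from .fcs import diffusion_coefficient

    d = diffusion_coefficient(sol.grid.tau_grid, focal)
    df = pd.DataFrame(
        {"tau_s": sol.grid.tau_grid, "alpha": sol.amplitudes, "rho": sol.rho, "D_um2s": d}
    )
    df.to_csv(path, index=False, float_format="%.10g")


def write_population_json(path, pop: PopulationSummary, extra: dict | None = None):
    payload = {
        "monomer_fraction": pop.monomer_fraction,
        "oligomer_fraction": pop.oligomer_fraction,
        "modal_d_monomer_um2s": pop.modal_d_monomer,
        "modal_d_oligomer_um2s": pop.modal_d_oligomer,
        "cutoff_d_um2s": pop.cutoff_d,
    }
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(_jsonify(payload), indent=2, sort_keys=True) + "\n")


def read_pull_xvg(path) -> PullTrace:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") and "=" in line:
                key, _, value = line.lstrip("# ").partition("=")
                try:
                    meta[key.strip()] = float(value)
                except ValueError:
                    pass
            elif not line.startswith(("@", "#")):
                break
    data = np.loadtxt(path, comments=("@", "#"))
    if data.ndim != 2 or data.shape[1] < 3:
        raise ValueError("pull file needs columns time, position, force")
    kwargs = {}
    if "spring_constant_kJ_mol_nm2" in meta:
        kwargs["spring_constant"] = meta["spring_constant_kJ_mol_nm2"]
    if "pull_rate_nm_ps" in meta:
        kwargs["pull_rate"] = meta["pull_rate_nm_ps"]
    return PullTrace(time=data[:, 0], position=data[:, 1], force=data[:, 2], **kwargs)


def write_pull_xvg(path, trace: PullTrace, comment: str | None = None):
    header = []
    if comment:
        header.append(f"# {comment}")
    header += [
        f"# spring_constant_kJ_mol_nm2 = {trace.spring_constant:g}",
        f"# pull_rate_nm_ps = {trace.pull_rate:g}",
        "@    title \"steered pulling trace\"",
        "@    xaxis  label \"time (ps)\"",
        "@    yaxis  label \"position (nm), force (kJ/mol/nm)\"",
    ]
    body = "\n".join(
        f"{t:.6f} {x:.8f} {f:.8f}" for t, x, f in zip(trace.time, trace.position, trace.force)
    )
    Path(path).write_text("\n".join(header) + "\n" + body + "\n")


def write_pmf_csv(path, pmf: PmfProfile):
    pd.DataFrame({"r_nm": pmf.r_grid, "dG_kJmol": pmf.delta_g}).to_csv(
        path, index=False, float_format="%.10g"
    )


_ELEMENTS = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C"}


def lattice_to_pdb(path, lattice: FibrilLattice):
    """Write a lattice as a PDB file, one strand per chain."""
    n = lattice.coords.shape[0]
    atoms = struc.AtomArray(n)
    atoms.coord = lattice.coords
    atoms.chain_id = np.array([_CHAIN_IDS[s % len(_CHAIN_IDS)] for s in lattice.strand_ids])
    atoms.res_id = lattice.residue_ids
    atoms.res_name = np.full(n, "ALA")
    atoms.atom_name = lattice.atom_names
    atoms.element = np.array([_ELEMENTS.get(a, "C") for a in lattice.atom_names])
    atoms.hetero = np.zeros(n, dtype=bool)
    f = pdb.PDBFile()
    f.set_structure(atoms)
    f.write(str(path))


def read_pdb_coordinates(path):
    """Read coordinates and per-atom labels from a PDB file.

    Returns ``(coords, chain_labels, residue_ids, atom_names)``; chains
    index molecules the same way strand ids do for built lattices.
    """
    f = pdb.PDBFile.read(str(path))
    atoms = f.get_structure(model=1)
    chains = atoms.chain_id
    _, chain_idx = np.unique(chains, return_inverse=True)
    return atoms.coord, chain_idx, atoms.res_id, atoms.atom_name


def _jsonify(obj):
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonify(obj.tolist())
    if isinstance(obj, (np.floating, np.integer)):
        obj = obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj
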