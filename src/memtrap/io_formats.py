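"""Readers and writers for every external file the pipeline touches.

Conventions fixed here and relied on everywhere else:

* residue indexing is 1-based (K1 ... Y37 for hIAPP);
* the internal length unit is nm; PDB files (Å) are converted at the boundary;
* TSV dialect: tab-separated, ``.`` for missing values, ``#`` comment lines,
  UTF-8.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import gemmi
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "PlateRun",
    "ShiftEntry",
    "ShiftTable",
    "IntensityTable",
    "StructureModel",
    "read_plate_csv",
    "write_plate_csv",
    "read_shift_table",
    "write_shift_table",
    "read_nmrstar_shifts",
    "read_intensity_table",
    "write_intensity_table",
    "read_pdb",
    "write_pdb",
    "load_radius_set",
]

MISSING = "."

_DATA_DIR = Path(__file__).parent / "data"

PROBE_LABELS = ("none", "ND", "Gd", "DSA")

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


class FormatError(ValueError):
    """Raised when an input file violates a format contract."""


# ---------------------------------------------------------------------------
# Plate-reader fluorescence runs
# ---------------------------------------------------------------------------

@dataclass
class PlateRun:
    """One plate-reader run: a shared time grid plus per-well fluorescence.

    ``meta`` maps each well id to its condition dictionary
    (peptide_conc_uM, nanodisc_id, nanodisc_equiv, pH, temperature_C,
    replicate_group).
    """

    times: np.ndarray                      # minutes, strictly increasing
    wells: dict[str, np.ndarray]           # well id -> fluorescence (a.u.)
    meta: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.wells = {w: np.asarray(f, dtype=float) for w, f in self.wells.items()}
        self.validate()

    def validate(self) -> None:
        if not self.wells:
            raise FormatError("no data columns")
        d = np.diff(self.times)
        bad = np.nonzero(d <= 0)[0]
        if bad.size:
            # +2: +1 for diff offset, +1 for 1-based data rows
            raise FormatError(f"time not strictly increasing at row {bad[0] + 2}")
        for well, f in self.wells.items():
            if f.shape != self.times.shape:
                raise FormatError(
                    f"well {well}: {f.size} readings for {self.times.size} time points"
                )
            if not np.all(np.isfinite(f)):
                raise FormatError(f"well {well}: non-finite fluorescence")
        missing = sorted(set(self.wells) - set(self.meta))
        if missing:
            raise FormatError(f"wells without metadata: {', '.join(missing)}")


def read_plate_csv(path: str | Path, meta_path: str | Path) -> PlateRun:
    """Read a plate CSV (``time_min`` column + one column per well) and its
    condition sidecar (YAML mapping well id -> condition dict)."""
    df = pd.read_csv(path)
    if df.shape[1] == 0 or df.columns[0] != "time_min":
        raise FormatError(f"{path}: first column must be named 'time_min'")
    well_cols = list(df.columns[1:])
    if not well_cols:
        raise FormatError("no data columns")
    with open(meta_path, encoding="utf-8") as fh:
        meta = yaml.safe_load(fh) or {}
    if not isinstance(meta, dict):
        raise FormatError(f"{meta_path}: sidecar must be a mapping well -> condition")
    return PlateRun(
        times=df["time_min"].to_numpy(float),
        wells={w: df[w].to_numpy(float) for w in well_cols},
        meta={w: dict(meta[w]) for w in well_cols if w in meta},
    )


def write_plate_csv(run: PlateRun, path: str | Path, meta_path: str | Path) -> None:
    df = pd.DataFrame({"time_min": run.times} | {w: run.wells[w] for w in run.wells})
    df.to_csv(path, index=False)   # default str() formatting round-trips exactly
    with open(meta_path, "w", encoding="utf-8") as fh:
        yaml.safe_dump({w: dict(m) for w, m in run.meta.items()}, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# Backbone chemical-shift tables
# ---------------------------------------------------------------------------

@dataclass
class ShiftEntry:
    residue_index: int            # 1-based
    aa: str                       # one-letter code
    dCA: float | None = None      # ppm
    dCB: float | None = None
    dH: float | None = None
    dN: float | None = None


@dataclass
class ShiftTable:
    """Assigned backbone shifts over a known sequence.

    Residues of the sequence with no entry are *unassigned*; entries carry
    whatever nuclei were observed (``None`` for absent ones).
    """

    entries: list[ShiftEntry]
    sequence: str

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen: set[int] = set()
        n = len(self.sequence)
        for e in self.entries:
            if e.residue_index in seen:
                raise FormatError(f"duplicate residue index {e.residue_index}")
            seen.add(e.residue_index)
            if not 1 <= e.residue_index <= n:
                raise FormatError(
                    f"residue index {e.residue_index} outside sequence 1..{n}"
                )
            expected = self.sequence[e.residue_index - 1]
            if e.aa != expected:
                raise FormatError(
                    f"residue {e.residue_index}: table says {e.aa}, "
                    f"sequence says {expected}"
                )
            if e.aa == "G" and e.dCB is not None:
                warnings.warn(
                    f"Gly {e.residue_index} has a Cb shift; dropped", stacklevel=2
                )
                e.dCB = None

    @property
    def assigned(self) -> set[int]:
        return {e.residue_index for e in self.entries}

    @property
    def unassigned(self) -> set[int]:
        return set(range(1, len(self.sequence) + 1)) - self.assigned


def _parse_opt(tok: str) -> float | None:
    return None if tok == MISSING or tok == "" else float(tok)


def _fmt_opt(v: float | None) -> str:
    # repr gives the shortest string that round-trips the double exactly
    return MISSING if v is None else repr(float(v))


def read_shift_table(path: str | Path, sequence: str | None = None) -> ShiftTable:
    """Read a chemical-shift TSV.

    The sequence may be given either as an argument or in a header comment
    line ``# sequence: KCNT...``. Columns: residue_index, aa, dCA, dCB and
    optionally dH, dN; missing values are ``.``.
    """
    header: list[str] | None = None
    entries: list[ShiftEntry] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.lower().startswith("sequence:"):
                    seq = body.split(":", 1)[1].strip()
                    if sequence is None:
                        sequence = seq
                continue
            toks = line.split("\t")
            if header is None:
                header = toks
                continue
            row = dict(zip(header, toks))
            entries.append(
                ShiftEntry(
                    residue_index=int(row["residue_index"]),
                    aa=row["aa"],
                    dCA=_parse_opt(row.get("dCA", MISSING)),
                    dCB=_parse_opt(row.get("dCB", MISSING)),
                    dH=_parse_opt(row.get("dH", MISSING)),
                    dN=_parse_opt(row.get("dN", MISSING)),
                )
            )
    if sequence is None:
        raise FormatError(f"{path}: no sequence given (argument or '# sequence:' line)")
    return ShiftTable(entries=entries, sequence=sequence)


def write_shift_table(table: ShiftTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# sequence: {table.sequence}\n")
        fh.write("residue_index\taa\tdCA\tdCB\tdH\tdN\n")
        for e in sorted(table.entries, key=lambda e: e.residue_index):
            fh.write(
                f"{e.residue_index}\t{e.aa}\t{_fmt_opt(e.dCA)}\t{_fmt_opt(e.dCB)}"
                f"\t{_fmt_opt(e.dH)}\t{_fmt_opt(e.dN)}\n"
            )


def read_nmrstar_shifts(path: str | Path, sequence: str | None = None) -> ShiftTable:
    """Minimal NMR-STAR v3 reader: extracts the ``Atom_chem_shift`` loop only.

    Everything else in the file is ignored. Recognised atoms: CA, CB, H, N.
    """
    tags: list[str] = []
    rows: list[list[str]] = []
    in_loop = False
    collecting_tags = False
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line == "loop_":
                in_loop, collecting_tags, tags, rows = True, True, [], []
                continue
            if not in_loop:
                continue
            if line.startswith("_"):
                if collecting_tags:
                    tags.append(line.split()[0])
                continue
            collecting_tags = False
            if line == "stop_":
                if any(t.startswith("_Atom_chem_shift.") for t in tags):
                    break
                in_loop = False
                continue
            rows.append(line.split())
    if not any(t.startswith("_Atom_chem_shift.") for t in tags):
        raise FormatError(f"{path}: no Atom_chem_shift loop found")
    idx = {t.split(".", 1)[1]: i for i, t in enumerate(tags)}
    for required in ("Comp_index_ID", "Comp_ID", "Atom_ID", "Val"):
        if required not in idx:
            raise FormatError(f"{path}: Atom_chem_shift loop lacks {required}")
    per_res: dict[int, dict] = {}
    for row in rows:
        if len(row) != len(tags):
            continue
        ri = int(row[idx["Comp_index_ID"]])
        comp = row[idx["Comp_ID"]].upper()
        atom = row[idx["Atom_ID"]].upper()
        if atom not in ("CA", "CB", "H", "N"):
            continue
        aa = THREE_TO_ONE.get(comp)
        if aa is None:
            raise FormatError(f"{path}: unknown residue name {comp}")
        d = per_res.setdefault(ri, {"aa": aa})
        d["d" + atom] = float(row[idx["Val"]])
    if sequence is None:
        raise FormatError(f"{path}: sequence must be supplied for NMR-STAR input")
    entries = [
        ShiftEntry(
            residue_index=ri,
            aa=d["aa"],
            dCA=d.get("dCA"),
            dCB=d.get("dCB"),
            dH=d.get("dH"),
            dN=d.get("dN"),
        )
        for ri, d in sorted(per_res.items())
    ]
    return ShiftTable(entries=entries, sequence=sequence)


# ---------------------------------------------------------------------------
# HMQC peak-intensity tables
# ---------------------------------------------------------------------------

@dataclass
class IntensityTable:
    """Per-residue peak intensities from a 2D HMQC spectrum.

    ``extraction`` records whether peak heights or volumes were tabulated
    (the pipeline accepts either and propagates the label).
    """

    entries: dict[int, float]          # residue index -> intensity (a.u., >= 0)
    probe_label: str = "none"          # one of PROBE_LABELS
    probe_conc_uM: float = 0.0
    extraction: str = "height"         # "height" | "volume"

    def __post_init__(self) -> None:
        self.entries = {int(k): float(v) for k, v in self.entries.items()}
        self.validate()

    def validate(self) -> None:
        if self.probe_label not in PROBE_LABELS:
            raise FormatError(
                f"probe_label {self.probe_label!r} not in {PROBE_LABELS}"
            )
        for ri, v in self.entries.items():
            if v < 0:
                raise FormatError(f"residue {ri}: negative intensity {v}")


def read_intensity_table(path: str | Path) -> IntensityTable:
    probe_label, probe_conc, extraction = "none", 0.0, "height"
    entries: dict[int, float] = {}
    header: list[str] | None = None
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, val = (s.strip() for s in body.split(":", 1))
                    if key == "probe_label":
                        probe_label = val
                    elif key == "probe_conc_uM":
                        probe_conc = float(val)
                    elif key == "extraction":
                        extraction = val
                continue
            toks = line.split("\t")
            if header is None:
                header = toks
                continue
            row = dict(zip(header, toks))
            entries[int(row["residue_index"])] = float(row["intensity"])
    return IntensityTable(
        entries=entries,
        probe_label=probe_label,
        probe_conc_uM=probe_conc,
        extraction=extraction,
    )


def write_intensity_table(table: IntensityTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# probe_label: {table.probe_label}\n")
        fh.write(f"# probe_conc_uM: {table.probe_conc_uM:.10g}\n")
        fh.write(f"# extraction: {table.extraction}\n")
        fh.write("residue_index\tintensity\n")
        for ri in sorted(table.entries):
            fh.write(f"{ri}\t{table.entries[ri]:.10g}\n")


# ---------------------------------------------------------------------------
# Structures
# ---------------------------------------------------------------------------

GROUPS = ("peptide", "membrane", "solvent-excluded-other")


@dataclass
class StructureModel:
    """Column-oriented atom container in nm, with vdW radii and a coarse
    group label (peptide / membrane / other) per atom."""

    atom_name: list[str]
    residue_index: np.ndarray          # int, 1-based
    residue_name: list[str]
    chain_id: list[str]
    xyz: np.ndarray                    # (n, 3) nm
    vdw_radius: np.ndarray             # nm
    group: list[str]
    title: str = ""

    def __post_init__(self) -> None:
        self.residue_index = np.asarray(self.residue_index, dtype=int)
        self.xyz = np.asarray(self.xyz, dtype=float)
        self.vdw_radius = np.asarray(self.vdw_radius, dtype=float)
        self.validate()

    def validate(self) -> None:
        n = self.natoms
        if self.xyz.shape != (n, 3):
            raise FormatError("xyz must be (n_atoms, 3)")
        if not np.all(np.isfinite(self.xyz)):
            raise FormatError("non-finite coordinates")
        if np.any(self.vdw_radius <= 0):
            raise FormatError("vdW radii must be positive")
        for g in self.group:
            if g not in GROUPS:
                raise FormatError(f"unknown atom group {g!r}")

    @property
    def natoms(self) -> int:
        return len(self.atom_name)

    def select(self, groups: Sequence[str]) -> np.ndarray:
        """Boolean mask of atoms whose group is in ``groups``."""
        want = set(groups)
        return np.array([g in want for g in self.group], dtype=bool)

    def residues(self, mask: np.ndarray | None = None) -> list[int]:
        idx = self.residue_index if mask is None else self.residue_index[mask]
        return sorted(set(int(i) for i in idx))


def load_radius_set(name: str) -> tuple[Mapping[str, float], float]:
    """Return (element -> radius nm, default radius nm) for a named set."""
    with open(_DATA_DIR / "vdw_radii.json", encoding="utf-8") as fh:
        sets = json.load(fh)
    if name not in sets:
        raise FormatError(f"unknown radius set {name!r}; have {sorted(sets)}")
    entry = sets[name]
    return entry["radii"], float(entry["default"])


def _element_of(atom_name: str, element: str) -> str:
    if element:
        return element.upper()
    stripped = atom_name.strip()
    return stripped[:1].upper() if stripped else ""


def read_pdb(
    path: str | Path,
    group_rules: Mapping[str, str],
    radius_set: str = "bondi",
    default_radius: float | None = None,
    model_index: int = 0,
) -> StructureModel:
    """Read one model of a PDB file into a :class:`StructureModel`.

    Coordinates are converted Å→nm. ``group_rules`` maps a chain id or a
    residue name to one of ``peptide|membrane|solvent-excluded-other``;
    chain ids take precedence. Radii come from the named set, keyed by
    element; unknown elements get the set default (warning logged).
    """
    radii, set_default = load_radius_set(radius_set)
    if default_radius is None:
        default_radius = set_default
    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise FormatError(f"{path}: no models")
    model = st[model_index]
    names: list[str] = []
    res_idx: list[int] = []
    res_names: list[str] = []
    chains: list[str] = []
    coords: list[tuple[float, float, float]] = []
    rads: list[float] = []
    groups: list[str] = []
    warned_elements: set[str] = set()
    for chain in model:
        for res in chain:
            for atom in res:
                names.append(atom.name)
                res_idx.append(res.seqid.num)
                res_names.append(res.name)
                chains.append(chain.name)
                coords.append((atom.pos.x / 10.0, atom.pos.y / 10.0, atom.pos.z / 10.0))
                elem = _element_of(atom.name, atom.element.name)
                if elem in radii:
                    rads.append(radii[elem])
                else:
                    if elem not in warned_elements and radii:
                        warnings.warn(
                            f"element {elem!r} not in radius set {radius_set!r}; "
                            f"using default {default_radius} nm",
                            stacklevel=2,
                        )
                        warned_elements.add(elem)
                    rads.append(default_radius)
                if chain.name in group_rules:
                    groups.append(group_rules[chain.name])
                elif res.name in group_rules:
                    groups.append(group_rules[res.name])
                else:
                    raise FormatError(
                        f"atom {atom.name} (chain {chain.name}, residue {res.name}) "
                        f"matches no group rule; rules cover {sorted(group_rules)}"
                    )
    if not names:
        raise FormatError(f"{path}: no ATOM records")
    return StructureModel(
        atom_name=names,
        residue_index=np.array(res_idx),
        residue_name=res_names,
        chain_id=chains,
        xyz=np.array(coords),
        vdw_radius=np.array(rads),
        group=groups,
    )


def read_pdb_models(
    path: str | Path,
    group_rules: Mapping[str, str],
    radius_set: str = "bondi",
    default_radius: float | None = None,
) -> list[StructureModel]:
    """Read every model of a (possibly multi-model) PDB file."""
    st = gemmi.read_structure(str(path))
    return [
        read_pdb(path, group_rules, radius_set, default_radius, model_index=i)
        for i in range(len(st))
    ]


def write_pdb(
    model: StructureModel,
    path: str | Path,
    bfactors: np.ndarray | Sequence[float] | None = None,
) -> None:
    """Write a StructureModel as PDB v3.3 ATOM records (nm→Å).

    ``bfactors`` (per atom) land in the B-factor column; default 0.
    """
    b = np.zeros(model.natoms) if bfactors is None else np.asarray(bfactors, float)
    with open(path, "w", encoding="utf-8") as fh:
        for i in range(model.natoms):
            x, y, z = model.xyz[i] * 10.0
            name = model.atom_name[i]
            # PDB column-13 convention: 1-3 char names start in column 14
            name_f = f" {name:<3s}" if len(name) < 4 else f"{name:<4s}"
            fh.write(
                f"ATOM  {i + 1:5d} {name_f} {model.residue_name[i][:3]:>3s} "
                f"{model.chain_id[i][:1]:1s}{model.residue_index[i]:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{b[i]:6.2f}\n"
            )
        fh.write("END\n")
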