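"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the study design end-to-end: triplicate ThT plate
wells following the logistic model with Gaussian read noise; backbone
shift tables built from a random-coil reference plus signed
secondary-structure offsets; probe intensity tables where membrane
residues are broadened by the nanodisc and 5-DSA probes and solvent
residues by Gd(III); and a coarse-grained bead geometry of a peptide
chain laid on a planar two-layer bead slab standing in for the bilayer.

Every generator is a pure function of its spec (seed included): the same
spec yields bit-identical output. Default parameters are the study
conditions: the 37-residue hIAPP sequence, 4-minute readings over 48 h,
triplicate wells, strand offsets at residues 8-12 / 15-18 / 26-29, and
the membrane/solvent residue sets of the probe titrations. Note the
solvent set retains residue 19 as printed in the source data tables even
though residue 19 of the sequence is Ser (a known inconsistency in the
original residue list, reproduced deliberately).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .chemshift_ss import RandomCoilTable, load_random_coil
from .io_formats import IntensityTable, PlateRun, ShiftEntry, ShiftTable, StructureModel
from .tht_kinetics import eval_logistic

__all__ = [
    "HIAPP_SEQUENCE",
    "HIAPP_SS_STRING",
    "MEMBRANE_SET",
    "SOLVENT_SET",
    "ThtSpec",
    "ShiftSpec",
    "ProbeSpec",
    "GeometrySpec",
    "SimSpec",
    "derive_seed",
    "gen_tht_plate",
    "gen_shift_table",
    "gen_probe_tables",
    "gen_membrane_complex",
]

#: 37-residue human islet amyloid polypeptide (amylin), K1...Y37.
HIAPP_SEQUENCE = "KCNTATCATQRLANFLVHSSNNFGAILSSTNVGSNTY"

#: Three beta-strands (A8-L12, F15-H18, I26-S29), coil elsewhere.
HIAPP_SS_STRING = "CCCCCCCEEEEECCEEEECCCCCCCEEEECCCCCCCC"

#: Residues broadened by the nanodisc and 5-DSA probes (membrane-facing).
MEMBRANE_SET = frozenset({6, 11, 12, 13, 17, 18})

#: Residues broadened by the Gd(III) solvent PRE (solvent-facing).
SOLVENT_SET = frozenset({19, 22, 23, 25, 26, 30, 31, 33, 34, 35, 36, 37})


def derive_seed(seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31, hashed from (seed, stage name)."""
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


# ---------------------------------------------------------------------------
# Spec blocks (defaults = study conditions)
# ---------------------------------------------------------------------------

def _default_tht_conditions() -> list[dict]:
    # Untreated hIAPP aggregates within the run; one nanodisc-treated
    # condition is slowed, another (the stabilizing composition) never
    # fibrillates within the 48 h window.
    return [
        {"name": "untreated", "nanodisc_id": "none", "nanodisc_equiv": 0.0,
         "F0": 0.02, "Finf": 0.98, "k": 0.02, "t50": 300.0},
        {"name": "ND1_1eq", "nanodisc_id": "ND1", "nanodisc_equiv": 1.0,
         "F0": 0.02, "Finf": 0.98, "k": 0.008, "t50": 900.0},
        {"name": "ND1_10eq", "nanodisc_id": "ND1", "nanodisc_equiv": 10.0,
         "F0": 0.02, "Finf": 0.02, "k": 0.008, "t50": 900.0},  # censored: flat
    ]


@dataclass
class ThtSpec:
    conditions: list[dict] = field(default_factory=_default_tht_conditions)
    noise_sigma: float = 0.02
    n_replicates: int = 3
    t_start: float = 0.0
    t_step: float = 4.0            # minutes between reads
    n_times: int = 721             # 48 h at 4-min intervals
    pH: float = 5.3
    temperature_C: float = 35.0
    peptide_conc_uM: float = 5.0


@dataclass
class ShiftSpec:
    sequence: str = HIAPP_SEQUENCE
    ss_string: str = HIAPP_SS_STRING
    # signed full-offset magnitudes (ppm): strand Ca down / Cb up, helix opposite
    strand_offset_ca: float = -1.8
    strand_offset_cb: float = 1.5
    helix_offset_ca: float = 2.6
    helix_offset_cb: float = -0.4
    coil_noise_sigma: float = 0.3
    unassigned: frozenset[int] = frozenset({1, 2, 3, 4, 5, 35, 36, 37})
    rc_name: str = "wishart95"


@dataclass
class ProbeSpec:
    sequence: str = HIAPP_SEQUENCE
    membrane: frozenset[int] = MEMBRANE_SET
    solvent: frozenset[int] = SOLVENT_SET
    broadening_factor: float = 0.3     # I_probe = factor * I_ref on affected residues
    noise_sigma: float = 0.05
    base_intensity: float = 100.0
    independent_noise: bool = False    # fresh noise per table instead of shared
    unobserved: frozenset[int] = frozenset()


@dataclass
class GeometrySpec:
    n_residues: int = 37
    contacts: frozenset[int] = frozenset(range(11, 20))   # residues 11-19
    peptide_bead_radius: float = 0.23     # nm, Martini-like backbone bead
    slab_bead_radius: float = 0.26        # nm, lipid bead
    bead_spacing: float = 0.55            # nm along the chain
    slab_spacing: float = 0.50            # nm hexagonal grid pitch
    contact_gap: float = 0.24             # nm below touching distance: contact
                                          # beads sit half-sunk in the head-
                                          # group layer so their membrane-facing
                                          # hemisphere is occluded
    lift_height: float = 1.6              # nm elevation of non-contact residues
    max_bond_dz: float = 2.0              # nm, chain-connectivity limit
    jitter_sigma: float = 0.0             # nm positional noise (off by default)


@dataclass
class SimSpec:
    """Top-level simulation spec; a single seed drives every stage via
    stage-name-hashed derived seeds."""

    seed: int
    tht: ThtSpec = field(default_factory=ThtSpec)
    shifts: ShiftSpec = field(default_factory=ShiftSpec)
    probes: ProbeSpec = field(default_factory=ProbeSpec)
    geometry: GeometrySpec = field(default_factory=GeometrySpec)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("SimSpec.seed is mandatory")
        if len(self.shifts.ss_string) != len(self.shifts.sequence):
            raise ValueError("ss_string length must equal sequence length")
        bad = set(self.shifts.ss_string) - set("HEC")
        if bad:
            raise ValueError(f"unknown secondary-structure symbols {sorted(bad)}")
        if not 0 < self.probes.broadening_factor <= 1:
            raise ValueError("broadening factor must be in (0, 1]: probes only "
                             "reduce intensity")
        if self.tht.noise_sigma < 0 or self.probes.noise_sigma < 0:
            raise ValueError("noise sigma must be non-negative")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["shifts"]["unassigned"] = sorted(self.shifts.unassigned)
        d["probes"]["membrane"] = sorted(self.probes.membrane)
        d["probes"]["solvent"] = sorted(self.probes.solvent)
        d["probes"]["unobserved"] = sorted(self.probes.unobserved)
        d["geometry"]["contacts"] = sorted(self.geometry.contacts)
        return d


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def gen_tht_plate(spec: SimSpec) -> tuple[PlateRun, pd.DataFrame]:
    """Plate of n_replicates wells per condition following the logistic
    truth parameters plus N(0, σ) read noise. Returns (PlateRun, truth)."""
    s = spec.tht
    rng = np.random.default_rng(derive_seed(spec.seed, "tht"))
    times = s.t_start + s.t_step * np.arange(s.n_times)
    wells: dict[str, np.ndarray] = {}
    meta: dict[str, dict] = {}
    truth_rows = []
    for ci, cond in enumerate(s.conditions):
        for rep in range(s.n_replicates):
            well = f"{chr(ord('A') + ci)}{rep + 1}"
            clean = eval_logistic(times, cond["F0"], cond["Finf"],
                                  cond["k"], cond["t50"])
            noise = rng.normal(0.0, s.noise_sigma, size=times.size) \
                if s.noise_sigma > 0 else 0.0
            wells[well] = np.asarray(clean + noise, dtype=float)
            meta[well] = {
                "peptide_conc_uM": s.peptide_conc_uM,
                "nanodisc_id": cond["nanodisc_id"],
                "nanodisc_equiv": cond["nanodisc_equiv"],
                "pH": s.pH,
                "temperature_C": s.temperature_C,
                "replicate_group": cond["name"],
            }
            flat = cond["Finf"] == cond["F0"]
            truth_rows.append(
                {
                    "well": well,
                    "condition": cond["name"],
                    "F0": cond["F0"],
                    "Finf": cond["Finf"],
                    "k": cond["k"],
                    "t50": cond["t50"],
                    "t_lag": np.nan if flat else cond["t50"] - 2.0 / cond["k"],
                    "censored": flat,
                }
            )
    return PlateRun(times=times, wells=wells, meta=meta), pd.DataFrame(truth_rows)


_SS_OFFSETS = {"C": (0.0, 0.0)}


def _offsets_for(spec: ShiftSpec, ss: str) -> tuple[float, float]:
    if ss == "E":
        return spec.strand_offset_ca, spec.strand_offset_cb
    if ss == "H":
        return spec.helix_offset_ca, spec.helix_offset_cb
    return 0.0, 0.0


def gen_shift_table(
    spec: SimSpec, rc: RandomCoilTable | None = None
) -> tuple[ShiftTable, str]:
    """Shift table δ = rc(aa) + offset(ss) + N(0, σ_coil), with the
    unassigned residues omitted. Returns (ShiftTable, truth ss_string)."""
    s = spec.shifts
    if rc is None:
        rc = load_random_coil(s.rc_name)
    rng = np.random.default_rng(derive_seed(spec.seed, "shifts"))
    entries: list[ShiftEntry] = []
    for i, (aa, ss) in enumerate(zip(s.sequence, s.ss_string), start=1):
        # draw noise for every residue so the unassigned set does not shift
        # the stream for the rest of the sequence
        eps_ca, eps_cb = rng.normal(0.0, s.coil_noise_sigma, size=2)
        if i in s.unassigned:
            continue
        off_ca, off_cb = _offsets_for(s, ss)
        dCA = rc.rcCA[aa] + off_ca + eps_ca
        dCB = None if aa == "G" else rc.rcCB[aa] + off_cb + eps_cb
        entries.append(ShiftEntry(residue_index=i, aa=aa, dCA=dCA, dCB=dCB))
    return ShiftTable(entries=entries, sequence=s.sequence), s.ss_string


def gen_probe_tables(
    spec: SimSpec,
) -> tuple[IntensityTable, IntensityTable, IntensityTable, IntensityTable, dict[int, str]]:
    """Reference + three probe intensity tables with known topology truth.

    The reference carries multiplicative read noise; each probe table is
    the reference scaled by the broadening factor on its affected residues
    (nanodisc and 5-DSA: membrane set; Gd: solvent set). With
    ``independent_noise`` every table instead draws its own noise.
    Returns (I_ref, I_ND, I_Gd, I_DSA, truth labels).
    """
    s = spec.probes
    rng = np.random.default_rng(derive_seed(spec.seed, "probes"))
    n = len(s.sequence)
    observed = [i for i in range(1, n + 1) if i not in s.unobserved]

    def noisy_base() -> dict[int, float]:
        eps = rng.normal(0.0, s.noise_sigma, size=len(observed)) \
            if s.noise_sigma > 0 else np.zeros(len(observed))
        return {
            ri: max(s.base_intensity * (1.0 + e), 0.0)
            for ri, e in zip(observed, eps)
        }

    ref = noisy_base()
    tables: dict[str, IntensityTable] = {}
    for label, affected in (("ND", s.membrane), ("Gd", s.solvent),
                            ("DSA", s.membrane)):
        base = noisy_base() if s.independent_noise else ref
        entries = {
            ri: base[ri] * (s.broadening_factor if ri in affected else 1.0)
            for ri in observed
        }
        tables[label] = IntensityTable(
            entries=entries, probe_label=label, probe_conc_uM=0.0
        )
    truth: dict[int, str] = {}
    for ri in range(1, n + 1):
        if ri in s.unobserved:
            truth[ri] = "unassigned"
        elif ri in s.membrane and ri in s.solvent:
            truth[ri] = "ambiguous"
        elif ri in s.membrane:
            truth[ri] = "membrane"
        elif ri in s.solvent:
            truth[ri] = "solvent"
        else:
            truth[ri] = "unclassified"
    return (
        IntensityTable(entries=ref, probe_label="none"),
        tables["ND"],
        tables["Gd"],
        tables["DSA"],
        truth,
    )


def gen_membrane_complex(
    spec: SimSpec,
) -> tuple[StructureModel, StructureModel, set[int]]:
    """Coarse bead geometry: a one-bead-per-residue peptide chain over a
    two-layer hexagonal bead slab standing in for the bilayer.

    Contact residues sit just above the slab's top bead-center plane
    (within touching distance minus ``contact_gap``); the rest of the
    chain is lifted by ``lift_height``. Returns
    (peptide alone, peptide+slab, truth contact set).
    """
    g = spec.geometry
    rng = np.random.default_rng(derive_seed(spec.seed, "geometry"))
    touch = g.peptide_bead_radius + g.slab_bead_radius
    z_contact = touch - g.contact_gap
    z_lift = z_contact + g.lift_height
    if abs(z_lift - z_contact) > g.max_bond_dz:
        raise ValueError(
            "contact displacement infeasible for chain connectivity: "
            f"|dz| = {abs(z_lift - z_contact):.2f} nm exceeds "
            f"{g.max_bond_dz} nm per bond"
        )
    xs = g.bead_spacing * np.arange(g.n_residues)
    zs = np.array([
        z_contact if (i + 1) in g.contacts else z_lift
        for i in range(g.n_residues)
    ])
    pep_xyz = np.column_stack([xs, np.zeros(g.n_residues), zs])
    if g.jitter_sigma > 0:
        pep_xyz = pep_xyz + rng.normal(0.0, g.jitter_sigma, size=pep_xyz.shape)

    # hexagonal slab under the chain, extended past both chain ends
    margin = 1.5
    x_min, x_max = xs.min() - margin, xs.max() + margin
    y_min, y_max = -margin, margin
    a = g.slab_spacing
    slab_pts = []
    for layer, z in enumerate((0.0, -2.0 * g.slab_bead_radius * 0.9)):
        row = 0
        y = y_min
        while y <= y_max:
            x = x_min + (a / 2.0 if row % 2 else 0.0)
            while x <= x_max:
                slab_pts.append((x, y, z))
                x += a
            y += a * np.sqrt(3.0) / 2.0
            row += 1
    slab_xyz = np.array(slab_pts)

    def model(include_slab: bool, title: str) -> StructureModel:
        names = ["BB"] * g.n_residues
        res_idx = list(range(1, g.n_residues + 1))
        res_names = ["BEA"] * g.n_residues
        chains = ["A"] * g.n_residues
        xyz = pep_xyz
        radii = [g.peptide_bead_radius] * g.n_residues
        groups = ["peptide"] * g.n_residues
        if include_slab:
            m = len(slab_xyz)
            names = names + ["LIP"] * m
            res_idx = res_idx + list(range(1001, 1001 + m))
            res_names = res_names + ["SLB"] * m
            chains = chains + ["B"] * m
            xyz = np.vstack([pep_xyz, slab_xyz])
            radii = radii + [g.slab_bead_radius] * m
            groups = groups + ["membrane"] * m
        return StructureModel(
            atom_name=names,
            residue_index=np.array(res_idx),
            residue_name=res_names,
            chain_id=chains,
            xyz=xyz,
            vdw_radius=np.array(radii),
            group=groups,
            title=title,
        )

    alone = model(False, "synthetic peptide bead chain (alone)")
    complex_ = model(True, "synthetic peptide bead chain on bead slab")
    return alone, complex_, set(g.contacts)
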