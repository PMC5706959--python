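"""Solvent-accessible surface area and membrane-orientation analysis.

SASA is computed with a Shrake–Rupley-style quadrature: each atom's
accessible sphere (radius = vdW + augment + probe) is sampled with a
deterministic golden-spiral point set, and the accessible area is the
unoccluded fraction times the sphere area. The lipid-accessible area of
a membrane-bound peptide is the per-residue SASA lost on adding the
membrane: SASA(peptide alone) − SASA(peptide in complex), both computed
for the identical peptide conformation. Residues are then labeled by
environment preference and compared against the NMR topology call.

For coarse-grained (Martini) inputs the convention of enlarging every
bead radius by 0.21 nm is supported through ``radius_augment``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .io_formats import StructureModel

__all__ = [
    "SASAProfile",
    "AccessibilitySplit",
    "AgreementReport",
    "golden_spiral_points",
    "sasa",
    "mean_sasa",
    "accessibility_split",
    "topology_agreement",
]


def golden_spiral_points(n: int) -> np.ndarray:
    """``n`` near-uniform unit-sphere points from the golden-angle spiral.

    Deterministic and defined for any n >= 1; quadrature weights are 1/n.
    """
    if n < 1:
        raise ValueError("need at least one point")
    i = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


@dataclass
class SASAProfile:
    """Per-atom and per-residue accessible areas (nm²) with the quadrature
    parameters recorded."""

    atom_areas: np.ndarray              # nm², aligned with retained atoms
    atom_residue: np.ndarray            # residue index per retained atom
    residue_areas: dict[int, float]     # nm²
    params: dict = field(default_factory=dict)

    def total(self) -> float:
        return float(self.atom_areas.sum())


def _dedupe(xyz: np.ndarray, radii: np.ndarray) -> np.ndarray:
    """Mask dropping exact duplicates (same position, same radius)."""
    keep = np.ones(len(xyz), dtype=bool)
    seen: dict[tuple, int] = {}
    for i, (p, r) in enumerate(zip(xyz, radii)):
        key = (round(p[0], 9), round(p[1], 9), round(p[2], 9), round(r, 9))
        if key in seen:
            keep[i] = False
        else:
            seen[key] = i
    if not keep.all():
        warnings.warn(
            f"{(~keep).sum()} duplicate atoms removed before SASA", stacklevel=3
        )
    return keep


def sasa(
    structure: StructureModel,
    subset: Sequence[str] | None = None,
    probe_radius: float = 0.14,
    n_points: int = 960,
    radius_augment: float = 0.0,
    radius_set_name: str | None = None,
) -> SASAProfile:
    """Per-residue SASA of the atoms in ``subset`` groups (default: all).

    Occlusion is tested against *all* retained atoms, so computing the
    peptide subset of a peptide+membrane system yields the peptide's area
    in the complex. Effective atom radius is vdW + ``radius_augment``;
    the probe is added on top.
    """
    if n_points < 32:
        raise ValueError("quadrature too coarse: need n_points >= 32")
    if subset is None:
        mask = np.ones(structure.natoms, dtype=bool)
    else:
        mask = structure.select(subset)
        if not mask.any():
            raise ValueError(f"no atoms left after filtering groups {subset}")
    xyz = structure.xyz
    R = structure.vdw_radius + radius_augment + probe_radius   # accessible radii
    keep = _dedupe(xyz, structure.vdw_radius)
    unit = golden_spiral_points(n_points)

    target = np.nonzero(mask & keep)[0]
    occluders_xyz = xyz[keep]
    occluders_R = R[keep]
    areas = np.zeros(len(target))
    for out_i, i in enumerate(target):
        d = np.linalg.norm(occluders_xyz - xyz[i], axis=1)
        near = (d < R[i] + occluders_R) & (d > 0)
        pts = xyz[i] + R[i] * unit
        if near.any():
            diff = pts[:, None, :] - occluders_xyz[near][None, :, :]
            buried = (
                (diff * diff).sum(axis=2) < (occluders_R[near] ** 2)[None, :]
            ).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[out_i] = frac * 4.0 * np.pi * R[i] ** 2

    res_idx = structure.residue_index[target]
    residue_areas: dict[int, float] = {}
    for ri, a in zip(res_idx, areas):
        residue_areas[int(ri)] = residue_areas.get(int(ri), 0.0) + float(a)
    return SASAProfile(
        atom_areas=areas,
        atom_residue=res_idx,
        residue_areas=residue_areas,
        params={
            "probe_radius": probe_radius,
            "n_quadrature_points": n_points,
            "radius_augment": radius_augment,
            "radius_set": radius_set_name,
            "subset": list(subset) if subset is not None else None,
        },
    )


def mean_sasa(profiles: Iterable[SASAProfile]) -> SASAProfile:
    """Average per-residue areas over snapshots (e.g. multi-model PDB)."""
    profiles = list(profiles)
    if not profiles:
        raise ValueError("no snapshots given")
    first = profiles[0]
    for p in profiles[1:]:
        if _core_params(p.params) != _core_params(first.params):
            raise ValueError("snapshot SASA profiles computed with different "
                             "parameters")
    residues = sorted(first.residue_areas)
    mean_areas = {
        ri: float(np.mean([p.residue_areas.get(ri, 0.0) for p in profiles]))
        for ri in residues
    }
    return SASAProfile(
        atom_areas=np.array([]),
        atom_residue=np.array([], dtype=int),
        residue_areas=mean_areas,
        params=first.params | {"n_snapshots": len(profiles)},
    )


def _core_params(params: dict) -> tuple:
    return (
        params.get("probe_radius"),
        params.get("n_quadrature_points"),
        params.get("radius_augment"),
        params.get("radius_set"),
    )


@dataclass
class AccessibilitySplit:
    """Per-residue solvent vs lipid accessible area and the resulting
    environment preference."""

    solvent_area: dict[int, float]       # nm²: SASA in the complex
    lipid_area: dict[int, float]         # nm²: SASA(alone) - SASA(complex)
    preference: dict[int, str]           # lipid | solvent | mixed | buried
    min_area: float = 0.10
    clamped: set[int] = field(default_factory=set)

    def residues(self, pref: str) -> set[int]:
        return {ri for ri, p in self.preference.items() if p == pref}


def accessibility_split(
    peptide_alone: SASAProfile,
    complex_peptide: SASAProfile,
    min_area: float = 0.10,
    clamp_tol: float = 0.02,
) -> AccessibilitySplit:
    """Split each residue's accessible area into solvent and lipid parts.

    Both profiles must come from identical quadrature parameters and the
    identical peptide conformation. Small negative lipid areas (within the
    quadrature tolerance ``clamp_tol`` nm²) are clamped to zero silently;
    larger ones are clamped with a warning.
    """
    if _core_params(peptide_alone.params) != _core_params(complex_peptide.params):
        raise ValueError("SASA parameter mismatch between alone and complex "
                         "profiles")
    res_a = set(peptide_alone.residue_areas)
    res_c = set(complex_peptide.residue_areas)
    if res_a != res_c:
        raise ValueError(
            f"residue support mismatch: only-alone {sorted(res_a - res_c)}, "
            f"only-complex {sorted(res_c - res_a)}"
        )
    solvent: dict[int, float] = {}
    lipid: dict[int, float] = {}
    pref: dict[int, str] = {}
    clamped: set[int] = set()
    for ri in sorted(res_a):
        s = complex_peptide.residue_areas[ri]
        l = peptide_alone.residue_areas[ri] - s
        if l < 0:
            if l < -clamp_tol:
                warnings.warn(
                    f"residue {ri}: lipid area {l:.3f} nm² below -{clamp_tol}; "
                    "clamped to 0 (check conformations match)",
                    stacklevel=2,
                )
                clamped.add(ri)
            l = 0.0
        solvent[ri] = s
        lipid[ri] = l
        if s < min_area and l < min_area:
            pref[ri] = "buried"
        elif (
            s >= min_area
            and l >= min_area
            and abs(l - s) <= 0.25 * max(l, s)
        ):
            pref[ri] = "mixed"
        elif l >= s and l >= min_area:
            pref[ri] = "lipid"
        else:
            pref[ri] = "solvent"
    return AccessibilitySplit(
        solvent_area=solvent,
        lipid_area=lipid,
        preference=pref,
        min_area=min_area,
        clamped=clamped,
    )


@dataclass
class AgreementReport:
    """Contingency of NMR membrane residues vs SASA lipid-preferring ones."""

    both: set[int]
    nmr_only: set[int]
    sasa_only: set[int]
    neither: set[int]
    overlap_coefficient: float | None     # |both| / min(|NMR|, |SASA|)
    undefined: bool = False

    def counts(self) -> dict[str, int]:
        return {
            "both": len(self.both),
            "nmr_only": len(self.nmr_only),
            "sasa_only": len(self.sasa_only),
            "neither": len(self.neither),
        }


def topology_agreement(nmr, split: AccessibilitySplit) -> AgreementReport:
    """Compare NMR-derived membrane residues with SASA lipid-preferring ones.

    ``nmr`` is a :class:`~memtrap.probe_topology.TopologyCall`. The overlap
    coefficient is |both| / min(|NMR set|, |SASA set|); an empty NMR set
    leaves it undefined (flagged).
    """
    support = set(split.preference)
    nmr_set = {ri for ri in nmr.residues("membrane") if ri in support}
    sasa_set = split.residues("lipid")
    both = nmr_set & sasa_set
    if not nmr_set:
        overlap, undefined = None, True
    else:
        denom = min(len(nmr_set), len(sasa_set))
        overlap = len(both) / denom if denom else 0.0
        undefined = False
    return AgreementReport(
        both=both,
        nmr_only=nmr_set - sasa_set,
        sasa_only=sasa_set - nmr_set,
        neither=support - nmr_set - sasa_set,
        overlap_coefficient=overlap,
        undefined=undefined,
    )
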