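"""Secondary chemical shifts and secondary-structure propensity.

The secondary shift of a nucleus is the observed shift minus its
random-coil reference, Δδ = δ_obs − δ_rc. The Cα−Cβ difference
Δδ(¹³Cα) − Δδ(¹³Cβ) is positive in α-helix and negative in β-strand, and
a windowed, reference-normalized combination of the two nuclei yields an
SSP-style propensity score in [−1, +1] (+1 fully helical, −1 fully
extended). Contiguous runs of strand- or helix-like residues are then
called as segments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import MISSING, ShiftTable

__all__ = [
    "RandomCoilTable",
    "SSPReference",
    "SecondaryShiftProfile",
    "Segment",
    "SegmentCall",
    "load_random_coil",
    "load_ssp_reference",
    "secondary_shifts",
    "ssp_score",
    "call_segments",
]

_DATA_DIR = Path(__file__).parent / "data"

AA20 = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class RandomCoilTable:
    """Random-coil Cα/Cβ reference shifts (ppm) for the 20 amino acids."""

    name: str
    rcCA: dict[str, float]
    rcCB: dict[str, float]            # no entry for Gly

    def validate(self) -> None:
        missing = set(AA20) - set(self.rcCA)
        if missing:
            raise ValueError(f"random-coil table lacks Cα for {sorted(missing)}")
        missing_cb = set(AA20) - {"G"} - set(self.rcCB)
        if missing_cb:
            raise ValueError(f"random-coil table lacks Cβ for {sorted(missing_cb)}")
        if "G" in self.rcCB:
            raise ValueError("Gly must not have a Cβ reference")


@dataclass
class SSPReference:
    """Full-structure secondary-shift offsets (ppm) used to normalize
    propensity scores: refH is the fully-helical offset, refE the
    fully-extended one, per nucleus."""

    name: str
    refH: dict[str, float]            # nucleus -> ppm
    refE: dict[str, float]


def load_random_coil(name: str = "wishart95") -> RandomCoilTable:
    path = _DATA_DIR / f"random_coil_{name}.tsv"
    if not path.exists():
        raise ValueError(f"unknown random-coil table {name!r}")
    df = pd.read_csv(path, sep="\t", comment="#", na_values=[MISSING])
    table = RandomCoilTable(
        name=name,
        rcCA={r.aa: float(r.rcCA) for r in df.itertuples()},
        rcCB={r.aa: float(r.rcCB) for r in df.itertuples() if not math.isnan(r.rcCB)},
    )
    table.validate()
    return table


def load_ssp_reference(name: str = "ssp-consensus-v1") -> SSPReference:
    df = pd.read_csv(_DATA_DIR / "ssp_reference_offsets.tsv", sep="\t", comment="#")
    return SSPReference(
        name=name,
        refH={r.nucleus: float(r.refH) for r in df.itertuples()},
        refE={r.nucleus: float(r.refE) for r in df.itertuples()},
    )


@dataclass
class SecondaryShiftProfile:
    """Per-residue secondary shifts over the full sequence.

    Backed by a DataFrame indexed by residue (1-based) with columns
    aa, assigned, dCA_sec, dCB_sec, dCaCb, ssp (NaN where undefined).
    """

    data: pd.DataFrame
    sequence: str
    rc_name: str
    provenance: dict = field(default_factory=dict)

    def assigned_indices(self) -> list[int]:
        return [int(i) for i in self.data.index[self.data["assigned"]]]


def secondary_shifts(
    shifts: ShiftTable, rc: RandomCoilTable | str = "wishart95"
) -> SecondaryShiftProfile:
    """Compute Δδ per nucleus and the Cα−Cβ difference for every residue.

    For Gly (no Cβ) the difference column carries ΔδCα alone, flagged in
    the ``gly_ca_only`` column. Unassigned residues propagate as NaN.
    """
    if isinstance(rc, str):
        rc = load_random_coil(rc)
    seq = shifts.sequence
    present = {aa for aa in seq}
    missing_type = present - set(rc.rcCA)
    if missing_type:
        raise ValueError(f"residue types {sorted(missing_type)} absent from "
                         f"random-coil table {rc.name!r}")
    if not shifts.entries:
        raise ValueError("empty profile: no residues assigned")
    n = len(seq)
    idx = pd.RangeIndex(1, n + 1, name="residue_index")
    df = pd.DataFrame(
        {
            "aa": list(seq),
            "assigned": False,
            "dCA_sec": np.nan,
            "dCB_sec": np.nan,
            "dCaCb": np.nan,
            "gly_ca_only": False,
            "ssp": np.nan,
        },
        index=idx,
    )
    for e in shifts.entries:
        i = e.residue_index
        df.loc[i, "assigned"] = True
        if e.dCA is not None:
            df.loc[i, "dCA_sec"] = e.dCA - rc.rcCA[e.aa]
        if e.dCB is not None and e.aa != "G":
            df.loc[i, "dCB_sec"] = e.dCB - rc.rcCB[e.aa]
        ca, cb = df.loc[i, "dCA_sec"], df.loc[i, "dCB_sec"]
        if not math.isnan(ca):
            if e.aa == "G":
                df.loc[i, "dCaCb"] = ca
                df.loc[i, "gly_ca_only"] = True
            elif not math.isnan(cb):
                df.loc[i, "dCaCb"] = ca - cb
            else:
                df.loc[i, "dCaCb"] = ca
    return SecondaryShiftProfile(
        data=df, sequence=seq, rc_name=rc.name,
        provenance={"rc_table": rc.name, "neighbor_correction": False},
    )


def _residue_score(
    dca: float, dcb: float, ref: SSPReference, nuclei: tuple[str, ...]
) -> float:
    """Normalized per-residue score: +1 at the full-helix reference, −1 at
    the full-strand reference, averaged over available nuclei."""
    scores = []
    if "CA" in nuclei and not math.isnan(dca):
        # Cα: helix-ward is positive
        scores.append(dca / ref.refH["CA"] if dca >= 0 else dca / abs(ref.refE["CA"]))
    if "CB" in nuclei and not math.isnan(dcb):
        # Cβ: helix-ward is negative; strand contributions enter negated
        if dcb <= 0:
            scores.append(dcb / ref.refH["CB"])      # refH['CB'] < 0 -> positive
        else:
            scores.append(-(dcb / abs(ref.refE["CB"])))
    return float(np.mean(scores)) if scores else math.nan


def ssp_score(
    profile: SecondaryShiftProfile,
    window: int = 5,
    nuclei: tuple[str, ...] = ("CA", "CB"),
    reference: SSPReference | None = None,
) -> SecondaryShiftProfile:
    """Fill the ``ssp`` column with the windowed propensity score.

    Each assigned residue gets a reference-normalized score per nucleus;
    the residue scores are averaged over the ±(window−1)/2 neighborhood
    restricted to assigned residues and clipped to [−1, 1].
    """
    if window < 3 or window % 2 == 0:
        raise ValueError(f"window must be an odd integer >= 3, got {window}")
    if reference is None:
        reference = load_ssp_reference()
    df = profile.data
    raw = {
        int(i): _residue_score(
            float(df.loc[i, "dCA_sec"]), float(df.loc[i, "dCB_sec"]),
            reference, nuclei,
        )
        for i in df.index
        if df.loc[i, "assigned"]
    }
    half = (window - 1) // 2
    ssp = pd.Series(np.nan, index=df.index)
    for i in df.index:
        vals = [
            raw[j]
            for j in range(int(i) - half, int(i) + half + 1)
            if j in raw and not math.isnan(raw[j])
        ]
        if vals:
            ssp.loc[i] = float(np.clip(np.mean(vals), -1.0, 1.0))
    out = profile.data.copy()
    out["ssp"] = ssp
    return SecondaryShiftProfile(
        data=out,
        sequence=profile.sequence,
        rc_name=profile.rc_name,
        provenance=profile.provenance
        | {"ssp_window": window, "ssp_nuclei": list(nuclei),
           "ssp_reference": reference.name},
    )


@dataclass
class Segment:
    start: int          # 1-based, inclusive
    end: int
    kind: str           # "strand" | "helix"


@dataclass
class SegmentCall:
    segments: list[Segment]
    labels: dict[int, str]         # residue -> E / H / C / U

    def residues(self, kind: str) -> set[int]:
        out: set[int] = set()
        for s in self.segments:
            if s.kind == kind:
                out |= set(range(s.start, s.end + 1))
        return out


def _trim_weak_edges(
    a: int,
    b: int,
    state: dict[int, str],
    values: pd.Series,
    fraction: float,
) -> tuple[int, int]:
    """Shrink [a, b] while a terminal residue's |value| is below
    ``fraction`` of the run's median |value| (bridged gaps skipped)."""
    if fraction <= 0:
        return a, b
    members = [i for i in range(a, b + 1) if state[i] != "U"]
    med = float(np.median([abs(float(values.loc[i])) for i in members]))
    floor = fraction * med
    while a < b and state[a] != "U" and abs(float(values.loc[a])) < floor:
        a += 1
        while a < b and state[a] == "U":
            a += 1
    while b > a and state[b] != "U" and abs(float(values.loc[b])) < floor:
        b -= 1
        while b > a and state[b] == "U":
            b -= 1
    return a, b


def call_segments(
    profile: SecondaryShiftProfile,
    strand_thr: float = -0.7,
    helix_thr: float = 0.7,
    use: str = "dCaCb",
    min_strand_len: int = 3,
    min_helix_len: int = 4,
    bridge_single_gap: bool = True,
    boundary_min_fraction: float = 0.5,
) -> SegmentCall:
    """Call strand/helix segments from runs of thresholded residues.

    With ``use='dCaCb'`` the default thresholds are ±0.7 ppm; with
    ``use='ssp'`` pass thresholds on the propensity scale (e.g. ±0.15).
    A single unassigned residue between two qualifying runs of the same
    type is bridged when ``bridge_single_gap`` is set.

    Edge guard: a run's terminal residue whose |signal| falls below
    ``boundary_min_fraction`` of the run's median |signal| is trimmed.
    A threshold sits necessarily within reach of coil noise, so segment
    edges would otherwise smear outward by whichever neighbors happen to
    cross it; a genuine strand/helix edge residue carries close to the
    full secondary shift and is untouched. Set the fraction to 0 to
    disable.
    """
    if strand_thr >= 0 or helix_thr <= 0:
        raise ValueError(
            f"strand threshold must be negative and helix positive, got "
            f"{strand_thr} / {helix_thr}"
        )
    if use not in ("dCaCb", "ssp"):
        raise ValueError(f"use must be 'dCaCb' or 'ssp', got {use!r}")
    df = profile.data
    n = len(profile.sequence)
    state: dict[int, str] = {}
    for i in range(1, n + 1):
        if not bool(df.loc[i, "assigned"]):
            state[i] = "U"
            continue
        v = float(df.loc[i, use])
        if math.isnan(v):
            state[i] = "U"
        elif v <= strand_thr:
            state[i] = "e"
        elif v >= helix_thr:
            state[i] = "h"
        else:
            state[i] = "c"

    def runs_of(sym: str) -> list[tuple[int, int]]:
        out: list[tuple[int, int]] = []
        i = 1
        while i <= n:
            if state[i] == sym:
                j = i
                while j + 1 <= n and state[j + 1] == sym:
                    j += 1
                out.append((i, j))
                i = j + 1
            else:
                i += 1
        return out

    segments: list[Segment] = []
    for sym, kind, min_len in (
        ("e", "strand", min_strand_len),
        ("h", "helix", min_helix_len),
    ):
        runs = runs_of(sym)
        if bridge_single_gap:
            merged: list[tuple[int, int]] = []
            for run in runs:
                if (
                    merged
                    and run[0] - merged[-1][1] == 2
                    and state[run[0] - 1] == "U"
                ):
                    merged[-1] = (merged[-1][0], run[1])
                else:
                    merged.append(run)
            runs = merged
        for a, b in runs:
            a, b = _trim_weak_edges(
                a, b, state, df[use], boundary_min_fraction
            )
            if b - a + 1 >= min_len:
                segments.append(Segment(start=a, end=b, kind=kind))
    segments.sort(key=lambda s: s.start)

    labels = {i: ("U" if state[i] == "U" else "C") for i in range(1, n + 1)}
    for s in segments:
        sym = "E" if s.kind == "strand" else "H"
        for i in range(s.start, s.end + 1):
            if state[i] != "U":              # bridged gaps stay U
                labels[i] = sym
    return SegmentCall(segments=segments, labels=labels)
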