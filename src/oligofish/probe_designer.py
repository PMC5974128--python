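"""Probe selection on a degenerate consensus, and tandem-repeat probes.

Candidate FISH oligos are every consensus window of 24–31 nt (defaults)
that (i) contains no ``N``, (ii) has pool size (degeneracy) within the
synthesis cap, (iii) has its entire degenerate Tm range inside the
hybridization window — conservative, since every member of a pooled
degenerate probe must hybridize — and (iv) covers columns whose mean depth
is a sufficient fraction of the profile maximum, i.e. sits in a conserved
region.  Candidates are ranked by conservation (mean depth fraction) then
by Tm floor, and selected greedily with a minimum spacing, mirroring manual
region picking; the procedure is deterministic with leftmost-start
tie-breaks.

Tandem-repeat targets (telomeres, minisatellites) need no consensus: a
probe is a phase-truncated concatemer of the monomer, e.g. (TTTAGGG)4
truncated to a length whose Tm lands in the hybridization window.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import prod
from typing import Sequence

from .consensus_builder import ConsensusResult, ConservationProfile
from .iupac_seq import IUPAC_BASES, DegenerateSeq, FixedSeq
from .thermo import HybridizationConditions, MARMUR_DOTY_FISH, TmModel, TmRange, tm_fixed, tm_range

__all__ = [
    "DesignConstraints",
    "ProbeCandidate",
    "TandemMonomer",
    "TandemLengthScan",
    "enumerate_candidates",
    "scan_probes",
    "build_tandem_probe",
    "pick_tandem_length",
    "candidates_to_table",
    "candidates_to_bed",
]


@dataclass(frozen=True)
class DesignConstraints:
    """Probe design constraints.

    Defaults: 24–31 nt, Tm window 39–53 °C (at the chosen hybridization
    conditions), pool size <= 256, windows covering >= 50% of the maximum
    profile depth, and >= 20 nt spacing between selected probes.
    """

    len_min: int = 24
    len_max: int = 31
    tm_min: float = 39.0
    tm_max: float = 53.0
    max_degeneracy: int = 256
    min_depth_frac: float = 0.5
    min_spacing: int = 20

    def __post_init__(self):
        if self.len_min > self.len_max:
            raise ValueError("len_min must be <= len_max")
        if self.tm_min > self.tm_max:
            raise ValueError("tm_min must be <= tm_max")
        if self.len_min < 1 or self.max_degeneracy < 1 or self.min_spacing < 0:
            raise ValueError("invalid constraint value")


@dataclass(frozen=True)
class ProbeCandidate:
    """A designed oligo on the consensus (1-based inclusive coordinates)."""

    sequence: DegenerateSeq
    start: int
    end: int
    tm: TmRange
    mean_depth_frac: float
    score: float  #: primary ranking key (= mean_depth_frac)

    def __post_init__(self):
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError("coordinates inconsistent with sequence length")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TandemMonomer:
    """Primitive repeat unit of a tandem target (e.g. TTTAGGG, ACATTCTTGAT)."""

    unit: FixedSeq

    def __init__(self, unit: FixedSeq | str):
        u = unit if isinstance(unit, FixedSeq) else FixedSeq(str(unit))
        s = str(u)
        # primitivity: a string is a repetition of a shorter unit iff it
        # occurs in its own doubling at an offset < its length
        if (s + s).find(s, 1) != len(s):
            raise ValueError(f"monomer {s!r} is a repetition of a shorter unit")
        object.__setattr__(self, "unit", u)

    def __len__(self) -> int:
        return len(self.unit)

    def __str__(self) -> str:
        return str(self.unit)

    def concatemer(self, length: int, phase: int = 0) -> FixedSeq:
        """Length-``length`` window of the infinite repetition, from ``phase``."""
        s = str(self.unit)
        k = len(s)
        reps = (phase + length) // k + 2
        return FixedSeq((s * reps)[phase : phase + length])


def _window_degeneracy(letters: str) -> int:
    return prod(len(IUPAC_BASES[c]) for c in letters)


def enumerate_candidates(
    consensus: ConsensusResult,
    profile: ConservationProfile,
    constraints: DesignConstraints = DesignConstraints(),
    cond: HybridizationConditions = HybridizationConditions(),
    model: TmModel = MARMUR_DOTY_FISH,
) -> list[ProbeCandidate]:
    """Every constraint-passing window, before greedy selection.

    A window qualifies when it contains no ``N``, its degeneracy is within
    the cap, its whole Tm range lies inside the constraint window, and its
    mean depth fraction reaches the floor.  Relaxing any single constraint
    can only grow this pool.
    """
    letters = str(consensus.consensus)
    n = len(letters)
    depth = profile.depth.astype(float)
    max_depth = depth.max()
    if max_depth <= 0:
        return []
    candidates: list[ProbeCandidate] = []
    for start0 in range(n):
        for length in range(constraints.len_min, constraints.len_max + 1):
            end0 = start0 + length
            if end0 > n:
                break
            window = letters[start0:end0]
            if "N" in window:
                continue
            if _window_degeneracy(window) > constraints.max_degeneracy:
                continue
            try:
                rng = tm_range(window, cond, model)
            except ValueError:
                continue
            if rng.tm_min < constraints.tm_min or rng.tm_max > constraints.tm_max:
                continue
            ref_lo = consensus.span_start - 1 + start0
            mdf = float(depth[ref_lo : ref_lo + length].mean() / max_depth)
            if mdf < constraints.min_depth_frac:
                continue
            candidates.append(
                ProbeCandidate(
                    sequence=DegenerateSeq(window),
                    start=start0 + 1,
                    end=end0,
                    tm=rng,
                    mean_depth_frac=mdf,
                    score=mdf,
                )
            )
    return candidates


def scan_probes(
    consensus: ConsensusResult,
    profile: ConservationProfile,
    constraints: DesignConstraints = DesignConstraints(),
    cond: HybridizationConditions = HybridizationConditions(),
    model: TmModel = MARMUR_DOTY_FISH,
) -> list[ProbeCandidate]:
    """Enumerate, filter, rank, and greedily select probe candidates.

    Candidates from :func:`enumerate_candidates` are sorted by mean depth
    fraction (descending), then Tm floor (descending), then leftmost start,
    and selected greedily subject to ``min_spacing`` nt separation from
    every previously selected probe.  Deterministic; an empty result is
    valid.  Returned probes are in left-to-right consensus order.
    """
    candidates = enumerate_candidates(consensus, profile, constraints, cond, model)
    candidates.sort(key=lambda c: (-c.score, -c.tm.tm_min, c.start, c.end))
    selected: list[ProbeCandidate] = []
    for cand in candidates:
        ok = all(
            cand.start > s.end + constraints.min_spacing
            or cand.end < s.start - constraints.min_spacing
            for s in selected
        )
        if ok:
            selected.append(cand)
    selected.sort(key=lambda c: c.start)
    return selected


def build_tandem_probe(
    monomer: TandemMonomer | str, phase: int, target_len: int
) -> FixedSeq:
    """Phase-truncated concatemer probe for a tandem-repeat target.

    Returns the length-``target_len`` prefix of the infinite repetition of
    the monomer, started at offset ``phase``; the output is exactly
    periodic with the monomer length.
    """
    mono = monomer if isinstance(monomer, TandemMonomer) else TandemMonomer(monomer)
    k = len(mono)
    if not 0 <= phase < k:
        raise ValueError(f"phase must be in [0, {k})")
    if target_len < k:
        raise ValueError(f"target_len {target_len} shorter than monomer ({k} nt)")
    return mono.concatemer(target_len, phase)


@dataclass(frozen=True)
class TandemLengthScan:
    """Result of scanning tandem-probe lengths for Tm feasibility.

    ``per_length_tm`` records the phase-0 probe Tm for every length in the
    scanned range, whether or not a feasible length was found.
    """

    feasible: bool
    target_len: int | None
    tm: TmRange | None
    per_length_tm: dict[int, float]


def pick_tandem_length(
    monomer: TandemMonomer | str,
    cond: HybridizationConditions = HybridizationConditions(),
    model: TmModel = MARMUR_DOTY_FISH,
    constraints: DesignConstraints = DesignConstraints(),
) -> TandemLengthScan:
    """Smallest probe length in ``[len_min, len_max]`` whose Tm is in window.

    Scans phase-0 concatemer probes of each length; if no length lands the
    Tm inside ``[tm_min, tm_max]`` the result is infeasible and carries the
    per-length Tm report.
    """
    mono = monomer if isinstance(monomer, TandemMonomer) else TandemMonomer(monomer)
    per_length: dict[int, float] = {}
    hit: int | None = None
    for length in range(constraints.len_min, constraints.len_max + 1):
        if length < len(mono):
            continue
        tm = tm_fixed(mono.concatemer(length, 0), cond, model)
        per_length[length] = tm
        if hit is None and constraints.tm_min <= tm <= constraints.tm_max:
            hit = length
    if hit is None:
        return TandemLengthScan(False, None, None, per_length)
    return TandemLengthScan(True, hit, TmRange(per_length[hit], per_length[hit]), per_length)


# ---------------------------------------------------------------------------
# Export


def candidates_to_table(
    candidates: Sequence[ProbeCandidate],
    name_prefix: str = "probe",
    modification: str = "5′-Cy3",
    reverse_complement: bool = False,
):
    """Probe table DataFrame (printed-table layout: No., Probe, Sequence,
    Length, Position, Tm, Modification)."""
    import pandas as pd

    rows = []
    for i, c in enumerate(candidates, start=1):
        seq = c.sequence.reverse_complement() if reverse_complement else c.sequence
        rows.append(
            {
                "No.": i,
                "Probe": f"{name_prefix}_{i}",
                "Sequence": str(seq),
                "Length": c.length,
                "Position in consensus": f"{c.start}…{c.end}",
                "Tm (°C)": str(c.tm),
                "Modification": modification,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "No.",
            "Probe",
            "Sequence",
            "Length",
            "Position in consensus",
            "Tm (°C)",
            "Modification",
        ],
    )


def candidates_to_bed(
    candidates: Sequence[ProbeCandidate],
    path,
    chrom: str = "consensus",
    name_prefix: str = "probe",
) -> None:
    """Write probe positions as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for i, c in enumerate(candidates, start=1):
            fh.write(f"{chrom}\t{c.start - 1}\t{c.end}\t{name_prefix}_{i}\n")
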