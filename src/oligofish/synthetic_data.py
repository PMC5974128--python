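"""Seeded generators for homolog families and WGS read sets.

These generators provide ground-truth test beds for the whole pipeline
without any downloads: a star-shaped family of homologs diverged from a
known ancestor (emulating the conserved/divergent region structure of rDNA
repeat units, with GC-rich fully conserved windows standing in for the
conserved gene cores that real probes target), and read sets with a known
fraction of minisatellite concatemer reads planted among uniform random
background.  All output is a pure function of the spec, seed included.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .iupac_seq import FixedSeq
from .probe_designer import TandemMonomer
from .repeat_screen import ReadSet

__all__ = [
    "FamilySpec",
    "MutationRecord",
    "FamilyTruth",
    "ReadSimSpec",
    "simulate_family",
    "simulate_reads",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class FamilySpec:
    """Spec for a star-shaped homolog family.

    Each homolog is drawn independently from the ancestor: substitutions at
    ``per_lineage_sub_rate`` per site (a scalar applied to every lineage, or
    one rate per lineage), single-base indels at ``indel_rate`` per site
    (insertion or deletion with equal probability).  ``conserved_windows``
    (1-based inclusive, non-overlapping) are never mutated, and their
    ancestor bases are drawn GC-rich (``window_gc``) to emulate the GC-rich
    conserved cores of rDNA genes.
    """

    ancestor_length: int = 600
    n_lineages: int = 3
    per_lineage_sub_rate: float | tuple[float, ...] = 0.05
    indel_rate: float = 0.01
    conserved_windows: tuple[tuple[int, int], ...] = ((286, 315),)
    n_homologs_per_lineage: int = 20
    seed: int = 42
    background_gc: float = 0.5
    window_gc: float = 0.6

    def __post_init__(self):
        rates = self.sub_rates
        if len(rates) != self.n_lineages:
            raise ValueError("need one substitution rate per lineage")
        for r in (*rates, self.indel_rate):
            if not 0 <= r < 1:
                raise ValueError("rates must be in [0, 1)")
        last_end = 0
        for start, end in self.conserved_windows:
            if not 1 <= start <= end <= self.ancestor_length:
                raise ValueError(f"window {start}..{end} outside ancestor span")
            if start <= last_end:
                raise ValueError("conserved windows must be sorted and non-overlapping")
            last_end = end

    @property
    def sub_rates(self) -> tuple[float, ...]:
        r = self.per_lineage_sub_rate
        if isinstance(r, (int, float)):
            return (float(r),) * self.n_lineages
        return tuple(float(x) for x in r)


@dataclass(frozen=True)
class MutationRecord:
    """One realized mutation, in 1-based ancestor coordinates."""

    homolog_id: str
    position: int
    kind: str  #: "sub", "ins" (inserted after position), or "del"
    ref: str
    alt: str


@dataclass(frozen=True)
class FamilyTruth:
    """Ground truth of a simulated family."""

    mutations: tuple[MutationRecord, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "homolog_id": m.homolog_id,
                    "position": m.position,
                    "kind": m.kind,
                    "ref": m.ref,
                    "alt": m.alt,
                }
                for m in self.mutations
            ],
            columns=["homolog_id", "position", "kind", "ref", "alt"],
        )


def _conserved_mask(spec: FamilySpec) -> np.ndarray:
    mask = np.zeros(spec.ancestor_length, dtype=bool)
    for start, end in spec.conserved_windows:
        mask[start - 1 : end] = True
    return mask


def _draw_ancestor(spec: FamilySpec, rng: np.random.Generator) -> np.ndarray:
    """Ancestor bases: GC probability ``background_gc`` outside conserved
    windows and ``window_gc`` inside them."""
    gc_p = np.full(spec.ancestor_length, spec.background_gc)
    gc_p[_conserved_mask(spec)] = spec.window_gc
    is_gc = rng.random(spec.ancestor_length) < gc_p
    pick = rng.integers(0, 2, spec.ancestor_length)
    # GC -> C or G; AT -> A or T
    idx = np.where(is_gc, 1 + pick, 3 * pick)  # C=1,G=2 / A=0,T=3
    return idx


def simulate_family(
    spec: FamilySpec = FamilySpec(),
) -> tuple[FixedSeq, list[tuple[str, FixedSeq]], FamilyTruth]:
    """Simulate a homolog family; returns (ancestor, homologs, truth).

    Homolog ids are ``L{lineage}H{index}``; identical specs (seed included)
    give byte-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    anc_idx = _draw_ancestor(spec, rng)
    ancestor = FixedSeq("".join(_BASES[anc_idx]))
    conserved = _conserved_mask(spec)
    L = spec.ancestor_length
    homologs: list[tuple[str, FixedSeq]] = []
    mutations: list[MutationRecord] = []
    for lineage, sub_rate in enumerate(spec.sub_rates, start=1):
        for h in range(1, spec.n_homologs_per_lineage + 1):
            hom_id = f"L{lineage}H{h}"
            sub_here = (rng.random(L) < sub_rate) & ~conserved
            indel_here = (rng.random(L) < spec.indel_rate) & ~conserved
            is_ins = rng.random(L) < 0.5
            # per-site draws made unconditionally to keep the stream aligned
            sub_shift = rng.integers(1, 4, L)
            ins_base = rng.integers(0, 4, L)
            parts: list[str] = []
            for pos in range(L):
                ref_base = _BASES[anc_idx[pos]]
                base = ref_base
                if sub_here[pos]:
                    alt = _BASES[(anc_idx[pos] + sub_shift[pos]) % 4]
                    mutations.append(
                        MutationRecord(hom_id, pos + 1, "sub", ref_base, str(alt))
                    )
                    base = alt
                if indel_here[pos]:
                    if is_ins[pos]:
                        ins = _BASES[ins_base[pos]]
                        parts.append(str(base))
                        parts.append(str(ins))
                        mutations.append(
                            MutationRecord(hom_id, pos + 1, "ins", "-", str(ins))
                        )
                        continue
                    mutations.append(
                        MutationRecord(hom_id, pos + 1, "del", str(base), "-")
                    )
                    continue
                parts.append(str(base))
            homologs.append((hom_id, FixedSeq("".join(parts))))
    return ancestor, homologs, FamilyTruth(tuple(mutations))


@dataclass(frozen=True)
class ReadSimSpec:
    """Spec for a WGS read set with planted minisatellite concatemer reads.

    Planted reads start at a random phase of the monomer concatemer, on a
    random strand, with per-base substitution errors at ``error_rate``;
    background reads are uniform random.  Read order is shuffled, but read
    ids keep the ground truth (``planted_*`` / ``bg_*``).
    """

    n_reads: int = 10_000
    read_length: int = 100
    monomer: str = "ACATTCTTGAT"
    planted_fraction: float = 0.01
    error_rate: float = 0.01
    seed: int = 1
    sample_name: str = "sample"

    def __post_init__(self):
        if not 0 <= self.planted_fraction <= 1:
            raise ValueError("planted_fraction must be in [0, 1]")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")
        TandemMonomer(self.monomer)  # validates primitivity
        if self.read_length < len(self.monomer):
            raise ValueError("read_length must be >= monomer length")
        if self.n_reads < 1:
            raise ValueError("n_reads must be >= 1")


def simulate_reads(spec: ReadSimSpec = ReadSimSpec()) -> ReadSet:
    """Simulate a read set; deterministic given the spec."""
    rng = np.random.default_rng(spec.seed)
    mono = TandemMonomer(spec.monomer)
    k = len(mono)
    n_planted = int(round(spec.planted_fraction * spec.n_reads))
    entries: list[tuple[str, str]] = []
    for i in range(n_planted):
        phase = int(rng.integers(0, k))
        idx = _encode_read(str(mono.concatemer(spec.read_length, phase)))
        errs = rng.random(spec.read_length) < spec.error_rate
        shift = rng.integers(1, 4, spec.read_length)
        idx = np.where(errs, (idx + shift) % 4, idx)
        read = "".join(_BASES[idx])
        if rng.random() < 0.5:
            read = str(FixedSeq(read).reverse_complement())
        entries.append((f"planted_{i + 1}", read))
    for i in range(spec.n_reads - n_planted):
        idx = rng.integers(0, 4, spec.read_length)
        entries.append((f"bg_{i + 1}", "".join(_BASES[idx])))
    order = rng.permutation(len(entries))
    ids = tuple(entries[j][0] for j in order)
    reads = tuple(entries[j][1] for j in order)
    return ReadSet(sample_name=spec.sample_name, ids=ids, reads=reads)


def _encode_read(s: str) -> np.ndarray:
    lut = {b: i for i, b in enumerate("ACGT")}
    return np.array([lut[c] for c in s], dtype=np.int64)
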