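"""Minisatellite presence screening in WGS reads.

A short tandem monomer (e.g. the 11-bp Pgms1 unit ACATTCTTGAT) is detected
in a read when some window of at least ``min_span`` nt matches the infinite
concatemer of the monomer — at any rotation (phase) and on either strand —
with a mismatch fraction no larger than ``max_mismatch_frac``.  Matching is
ungapped: minisatellite copies are short and trying every phase absorbs
register shifts.  Screening a read set yields the fraction of evaluable
reads that match; a sample is called positive when that fraction clears a
presence threshold, by default a multiple of the empirical random-match
rate measured on base-shuffled copies of the same reads.  Comparing the
mapped fractions across samples from related species reproduces
species-specificity screens of newly discovered repeats.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import SeqIO

from .iupac_seq import FixedSeq, _as_seq
from .probe_designer import TandemMonomer

__all__ = [
    "ReadSet",
    "ScreenParams",
    "ScreenReport",
    "match_read",
    "screen_sample",
    "read_reads",
    "reports_to_tsv",
]

_LUT = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _LUT[_b] = _i
for _i, _b in enumerate(b"acgt"):
    _LUT[_b] = _i

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _encode(seq: str) -> np.ndarray:
    """Encode bases as 0..3 (anything else 4, which never matches)."""
    return _LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass
class ReadSet:
    """A named sample of reads."""

    sample_name: str
    ids: tuple[str, ...]
    reads: tuple[str, ...]

    def __post_init__(self):
        if len(self.reads) == 0:
            raise ValueError("read set must be nonempty")
        if len(self.ids) != len(self.reads):
            raise ValueError("ids and reads must have equal length")
        self.reads = tuple(str(_as_seq(r)) for r in self.reads)

    def __len__(self) -> int:
        return len(self.reads)


@dataclass(frozen=True)
class ScreenParams:
    """Screening parameters.

    ``min_span`` defaults to 30 nt (≈ three 11-mer monomer copies) and
    ``max_mismatch_frac`` to 0.1.  When ``presence_threshold`` is None it is
    set to ``background_multiplier`` times the random-match rate estimated
    on base-shuffled reads (floored at one read, so an all-negative sample
    is never called present); the shuffle is seeded for determinism.
    """

    min_span: int = 30
    max_mismatch_frac: float = 0.1
    presence_threshold: float | None = None
    background_multiplier: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.max_mismatch_frac < 1:
            raise ValueError("max_mismatch_frac must be in [0, 1)")
        if self.min_span < 1:
            raise ValueError("min_span must be >= 1")


@dataclass(frozen=True)
class ScreenReport:
    """Per-sample screening outcome."""

    sample_name: str
    total_reads: int
    evaluable_reads: int
    mapped_reads: int
    mapped_fraction: float
    presence_threshold: float
    present: bool


def _phase_matrix(monomer: TandemMonomer, length: int) -> np.ndarray:
    """Encoded concatemer windows, one row per phase, shape (k, length)."""
    k = len(monomer)
    base = _encode(str(monomer.concatemer(length + k, 0)))
    return np.stack([base[p : p + length] for p in range(k)])


def _windows_match(mm: np.ndarray, min_span: int, max_frac: float) -> np.ndarray:
    """For each leading row-set of mismatch indicators ``mm`` (..., L):
    does some window of length >= min_span have mismatch fraction <= max_frac?

    Uses prefix sums of (mismatch − max_frac): a qualifying window exists
    iff min over j−i >= min_span of P[j] − P[i] <= 0.
    """
    L = mm.shape[-1]
    if L < min_span:
        return np.zeros(mm.shape[:-1], dtype=bool)
    cost = mm.astype(np.float64) - max_frac
    P = np.concatenate(
        [np.zeros(mm.shape[:-1] + (1,)), np.cumsum(cost, axis=-1)], axis=-1
    )
    runmax = np.maximum.accumulate(P[..., : L - min_span + 1], axis=-1)
    vals = P[..., min_span:] - runmax
    return (vals <= 1e-9).any(axis=-1)


def _match_batch(
    encoded: np.ndarray, monomer: TandemMonomer, min_span: int, max_frac: float
) -> np.ndarray:
    """Match a batch of equal-length encoded reads; returns bool per read."""
    n, L = encoded.shape
    k = len(monomer)
    out = np.zeros(n, dtype=bool)
    if L < max(min_span, k):
        return out
    for mono in (monomer, TandemMonomer(str(_as_seq(str(monomer)).reverse_complement()))):
        phases = _phase_matrix(mono, L)  # (k, L)
        # chunk reads to bound the (chunk, k, L) mismatch tensor
        chunk = max(1, int(4_000_000 / (k * L)))
        for i in range(0, n, chunk):
            blk = encoded[i : i + chunk]
            mm = blk[:, None, :] != phases[None, :, :]
            hit = _windows_match(mm, min_span, max_frac).any(axis=-1)
            out[i : i + chunk] |= hit
    return out


def match_read(
    read: FixedSeq | str,
    monomer: TandemMonomer | str,
    min_span: int = 30,
    max_mismatch_frac: float = 0.1,
) -> bool:
    """True iff the read contains a concatemer match of the monomer.

    Every rotation of the monomer and both strands of the read are tried;
    the outcome is therefore invariant to rotating the monomer and to
    reverse-complementing the read.
    """
    mono = monomer if isinstance(monomer, TandemMonomer) else TandemMonomer(monomer)
    if min_span < len(mono):
        raise ValueError("min_span must be >= monomer length")
    s = str(_as_seq(read))
    enc = _encode(s)[None, :]
    return bool(_match_batch(enc, mono, min_span, max_mismatch_frac)[0])


def _shuffled_copy(reads: Sequence[str], rng: np.random.Generator) -> list[str]:
    out = []
    for r in reads:
        arr = np.frombuffer(r.encode("ascii"), dtype=np.uint8).copy()
        rng.shuffle(arr)
        out.append(arr.tobytes().decode("ascii"))
    return out


def _mapped_count(
    reads: Sequence[str], monomer: TandemMonomer, params: ScreenParams
) -> int:
    by_len: dict[int, list[int]] = {}
    for i, r in enumerate(reads):
        by_len.setdefault(len(r), []).append(i)
    mapped = 0
    for L, idxs in by_len.items():
        enc = np.stack([_encode(reads[i]) for i in idxs])
        mapped += int(
            _match_batch(enc, monomer, params.min_span, params.max_mismatch_frac).sum()
        )
    return mapped


def screen_sample(
    readset: ReadSet,
    monomer: TandemMonomer | str,
    params: ScreenParams = ScreenParams(),
) -> ScreenReport:
    """Screen a read set for the monomer and call presence.

    A read is evaluable when it is at least one monomer long; the mapped
    fraction is mapped/evaluable.  Deterministic given inputs (the
    background shuffle is seeded from ``params.seed``).
    """
    mono = monomer if isinstance(monomer, TandemMonomer) else TandemMonomer(monomer)
    if params.min_span < len(mono):
        raise ValueError("min_span must be >= monomer length")
    evaluable = [r for r in readset.reads if len(r) >= len(mono)]
    if not evaluable:
        raise ValueError(f"sample {readset.sample_name!r}: zero evaluable reads")
    mapped = _mapped_count(evaluable, mono, params)
    frac = mapped / len(evaluable)
    if params.presence_threshold is not None:
        threshold = params.presence_threshold
    else:
        rng = np.random.default_rng(params.seed)
        bg_mapped = _mapped_count(_shuffled_copy(evaluable, rng), mono, params)
        bg_rate = max(bg_mapped, 1) / len(evaluable)
        threshold = params.background_multiplier * bg_rate
    return ScreenReport(
        sample_name=readset.sample_name,
        total_reads=len(readset),
        evaluable_reads=len(evaluable),
        mapped_reads=mapped,
        mapped_fraction=frac,
        presence_threshold=threshold,
        present=frac >= threshold,
    )


def read_reads(path: str | Path, sample_name: str | None = None) -> ReadSet:
    """Load reads from FASTA or FASTQ (optionally gzip-compressed)."""
    path = Path(path)
    name = path.name
    opener = gzip.open if name.endswith(".gz") else open
    stem = name[:-3] if name.endswith(".gz") else name
    fmt = "fastq" if stem.endswith((".fq", ".fastq")) else "fasta"
    ids, reads = [], []
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, fmt):
            ids.append(rec.id)
            reads.append(str(rec.seq).upper())
    if sample_name is None:
        sample_name = stem.rsplit(".", 1)[0]
    return ReadSet(sample_name=sample_name, ids=tuple(ids), reads=tuple(reads))


def reports_to_tsv(reports: Sequence[ScreenReport], path: str | Path) -> None:
    """One row per sample: counts, mapped fraction, presence call."""
    import pandas as pd

    pd.DataFrame(
        [
            {
                "sample": r.sample_name,
                "total_reads": r.total_reads,
                "evaluable_reads": r.evaluable_reads,
                "mapped_reads": r.mapped_reads,
                "mapped_fraction": f"{r.mapped_fraction:.6g}",
                "presence_threshold": f"{r.presence_threshold:.6g}",
                "present": r.present,
            }
            for r in reports
        ]
    ).to_csv(path, sep="\t", index=False)
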