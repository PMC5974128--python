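"""Conservation-aware degenerate consensus from reference-mapped homologs.

Homologous sequences from many taxa (e.g. 18S/5.8S/5S rDNA records pulled
from public databases) are each mapped independently onto a single
reference repeat unit by semi-global alignment — read-mapping style, no
progressive MSA.  A homolog is accepted when at least ``min_match``
nucleotides align identically to the reference (default 50).  Accepted
homologs accumulate a per-column base-count profile in reference
coordinates; the profile is then collapsed to a degenerate IUPAC consensus
in which every base reaching a frequency threshold at a column is covered
by the emitted code.  Conserved regions show high depth and degeneracy-1
letters; polymorphic regions acquire ambiguity codes; uncovered flanks are
trimmed.

Coordinates are 1-based inclusive throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import Align

from .iupac_seq import CODE_FOR_BASES, DegenerateSeq, FixedSeq, _as_seq

__all__ = [
    "DEFAULT_MIN_MATCH",
    "AlignmentScoring",
    "MappingResult",
    "ConservationProfile",
    "ConsensusResult",
    "map_homolog",
    "build_profile",
    "build_consensus",
]

#: Minimum identically-aligned nucleotides for a homolog to be accepted.
DEFAULT_MIN_MATCH = 50

_BASE_ORDER = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASE_ORDER)}


@dataclass(frozen=True)
class AlignmentScoring:
    """Affine-gap scoring for homolog-to-reference mapping.

    Conventional DNA read-mapping weights; the stringency of the mapping
    is governed jointly by these and by ``min_match``.
    """

    match: float = 1.0
    mismatch: float = -2.0
    gap_open: float = -5.0
    gap_extend: float = -2.0


@dataclass(frozen=True)
class MappingResult:
    """Outcome of mapping one homolog onto the reference."""

    homolog_id: str
    ref_start: int  #: 1-based inclusive first reference column covered
    ref_end: int  #: 1-based inclusive last reference column covered
    matched_nt: int  #: identically aligned base pairs
    accepted: bool
    strand: str = "+"  #: "+" forward, "-" reverse-complement orientation


class ConservationProfile:
    """Per-column A/C/G/T counts over reference coordinates.

    ``counts`` has shape ``(ref_length, 4)`` in A, C, G, T order; ``depth``
    is the row sum.  Only accepted homologs contribute; insertions relative
    to the reference are invisible (the profile lives strictly in reference
    coordinates) and deletions leave columns un-incremented.
    """

    def __init__(self, ref_length: int, counts: np.ndarray | None = None):
        if ref_length < 1:
            raise ValueError("ref_length must be >= 1")
        self.ref_length = int(ref_length)
        if counts is None:
            counts = np.zeros((self.ref_length, 4), dtype=np.int64)
        counts = np.asarray(counts, dtype=np.int64)
        if counts.shape != (self.ref_length, 4):
            raise ValueError("counts must have shape (ref_length, 4)")
        self.counts = counts
        self.mappings: list[MappingResult] = []

    @property
    def depth(self) -> np.ndarray:
        """Accepted-homolog coverage per column, shape ``(ref_length,)``."""
        return self.counts.sum(axis=1)

    @property
    def n_accepted(self) -> int:
        return sum(m.accepted for m in self.mappings)

    @property
    def acceptance_fraction(self) -> float:
        if not self.mappings:
            return float("nan")
        return self.n_accepted / len(self.mappings)

    # -- I/O -------------------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        """Write the profile as a 1-based TSV: pos, A, C, G, T."""
        with open(path, "w") as fh:
            fh.write("pos\tA\tC\tG\tT\n")
            for i, row in enumerate(self.counts, start=1):
                fh.write(f"{i}\t{row[0]}\t{row[1]}\t{row[2]}\t{row[3]}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ConservationProfile":
        rows = []
        with open(path) as fh:
            header = fh.readline().split()
            if header != ["pos", "A", "C", "G", "T"]:
                raise ValueError(f"{path}: not a profile TSV (bad header)")
            for line in fh:
                pos, a, c, g, t = line.split()
                rows.append([int(a), int(c), int(g), int(t)])
        return cls(len(rows), np.array(rows, dtype=np.int64))

    def depth_to_bedgraph(self, path: str | Path, chrom: str = "consensus") -> None:
        """Write depth as bedGraph (0-based half-open, runs merged)."""
        depth = self.depth
        with open(path, "w") as fh:
            start = 0
            for i in range(1, self.ref_length + 1):
                if i == self.ref_length or depth[i] != depth[start]:
                    fh.write(f"{chrom}\t{start}\t{i}\t{depth[start]}\n")
                    start = i


@dataclass(frozen=True)
class ConsensusResult:
    """Degenerate consensus over the covered span of the reference.

    ``consensus[i]`` (0-based) corresponds to reference column
    ``span_start + i`` (1-based); columns outside ``span_start..span_end``
    had depth below ``min_depth`` at both flanks and are excluded.
    """

    consensus: DegenerateSeq
    span_start: int  #: 1-based first reference column with sufficient depth
    span_end: int  #: 1-based last reference column with sufficient depth

    def __post_init__(self):
        if len(self.consensus) != self.span_end - self.span_start + 1:
            raise ValueError("consensus length must equal covered span length")

    def to_ref_coord(self, consensus_pos: int) -> int:
        """Map a 1-based consensus position to a reference column."""
        return self.span_start + consensus_pos - 1


def _make_aligner(scoring: AlignmentScoring) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    aligner.open_gap_score = scoring.gap_open
    aligner.extend_gap_score = scoring.gap_extend
    # Free end gaps on both sequences: the homolog may start/end anywhere on
    # the reference and may overhang it (read-mapping semantics).
    aligner.end_insertion_score = 0.0
    aligner.end_deletion_score = 0.0
    return aligner


def _align_oriented(
    aligner: Align.PairwiseAligner, reference: str, homolog: str
):
    """Best alignment of homolog to reference; returns (alignment, matched_nt)."""
    alignment = aligner.align(reference, homolog)[0]
    matched = int(alignment.counts().identities)
    return alignment, matched


def map_homolog(
    homolog: FixedSeq | str,
    reference: FixedSeq | str,
    min_match: int = DEFAULT_MIN_MATCH,
    scoring: AlignmentScoring = AlignmentScoring(),
    homolog_id: str = "homolog",
) -> MappingResult:
    """Map one homolog onto the reference by semi-global affine alignment.

    Both orientations are tried; the one with more identically aligned
    nucleotides wins (ties resolve to forward).  The homolog is accepted iff
    ``matched_nt >= min_match``; rejection is a result, not an error.
    """
    hom = str(_as_seq(homolog))
    ref = str(_as_seq(reference))
    aligner = _make_aligner(scoring)
    fwd, fwd_matched = _align_oriented(aligner, ref, hom)
    rev_seq = str(_as_seq(hom).reverse_complement())
    rev, rev_matched = _align_oriented(aligner, ref, rev_seq)
    if rev_matched > fwd_matched:
        alignment, matched, strand = rev, rev_matched, "-"
    else:
        alignment, matched, strand = fwd, fwd_matched, "+"
    target_blocks = alignment.aligned[0]
    if len(target_blocks) == 0:
        return MappingResult(homolog_id, 0, 0, 0, False, strand)
    ref_start = int(target_blocks[0][0]) + 1
    ref_end = int(target_blocks[-1][1])
    return MappingResult(
        homolog_id, ref_start, ref_end, matched, matched >= min_match, strand
    )


def build_profile(
    homologs: Sequence[tuple[str, FixedSeq | str]] | Sequence[FixedSeq | str],
    reference: FixedSeq | str,
    min_match: int = DEFAULT_MIN_MATCH,
    scoring: AlignmentScoring = AlignmentScoring(),
) -> ConservationProfile:
    """Map every homolog and accumulate the conservation profile.

    ``homologs`` may be bare sequences or ``(id, sequence)`` pairs (as from
    :func:`oligofish.iupac_seq.read_fasta`).  Each accepted homolog
    increments the count of its aligned base at every aligned reference
    column; rejected homologs contribute nothing.  The returned profile
    carries the per-homolog :class:`MappingResult` list and the acceptance
    fraction.
    """
    if len(homologs) == 0:
        raise ValueError("homolog list must be nonempty")
    named: list[tuple[str, str]] = []
    for i, item in enumerate(homologs):
        if isinstance(item, tuple):
            named.append((str(item[0]), str(_as_seq(item[1]))))
        else:
            named.append((f"homolog_{i + 1}", str(_as_seq(item))))
    ref = str(_as_seq(reference))
    profile = ConservationProfile(len(ref))
    aligner = _make_aligner(scoring)
    for hom_id, hom in named:
        fwd, fwd_matched = _align_oriented(aligner, ref, hom)
        rev_seq = str(_as_seq(hom).reverse_complement())
        rev, rev_matched = _align_oriented(aligner, ref, rev_seq)
        if rev_matched > fwd_matched:
            alignment, matched, strand, seq = rev, rev_matched, "-", rev_seq
        else:
            alignment, matched, strand, seq = fwd, fwd_matched, "+", hom
        target_blocks, query_blocks = alignment.aligned
        if len(target_blocks) == 0:
            profile.mappings.append(
                MappingResult(hom_id, 0, 0, 0, False, strand)
            )
            continue
        ref_start = int(target_blocks[0][0]) + 1
        ref_end = int(target_blocks[-1][1])
        accepted = matched >= min_match
        profile.mappings.append(
            MappingResult(hom_id, ref_start, ref_end, matched, accepted, strand)
        )
        if not accepted:
            continue
        for (ts, te), (qs, qe) in zip(target_blocks, query_blocks):
            cols = np.arange(ts, te)
            idx = np.array(
                [_BASE_INDEX.get(b, -1) for b in seq[qs:qe]], dtype=np.int64
            )
            keep = idx >= 0  # non-ACGT homolog letters (e.g. N) are skipped
            np.add.at(profile.counts, (cols[keep], idx[keep]), 1)
    return profile


def build_consensus(
    profile: ConservationProfile,
    freq_threshold: float = 0.2,
    min_depth: int = 2,
) -> ConsensusResult:
    """Collapse a conservation profile into a degenerate IUPAC consensus.

    At every column with depth >= ``min_depth`` the emitted letter is the
    IUPAC code covering exactly the bases whose frequency reaches
    ``freq_threshold`` (the majority base — all of them on a tie — is always
    included, so the set is never empty).  Columns below ``min_depth`` are
    trimmed from the flanks and written as ``N`` internally.
    """
    if not 0 < freq_threshold <= 0.5:
        raise ValueError("freq_threshold must be in (0, 0.5]")
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    depth = profile.depth
    covered = np.flatnonzero(depth >= min_depth)
    if covered.size == 0:
        raise ValueError("no covered span: every column is below min_depth")
    span_start = int(covered[0]) + 1
    span_end = int(covered[-1]) + 1
    letters = []
    for col in range(span_start - 1, span_end):
        d = depth[col]
        if d < min_depth:
            letters.append("N")
            continue
        row = profile.counts[col]
        freqs = row / d
        bases = {
            _BASE_ORDER[i]
            for i in range(4)
            if freqs[i] >= freq_threshold or row[i] == row.max()
        }
        letters.append(CODE_FOR_BASES[frozenset(bases)])
    return ConsensusResult(DegenerateSeq("".join(letters)), span_start, span_end)
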