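"""Multiplex probe panels: probe-table I/O, cocktail pooling, crosstalk cap.

A probe table (tab-separated, printed-table layout: No., Probe, Sequence,
Length, Position in consensus, Tm, Modification) is parsed into
:class:`ProbeRecord` objects.  The probe name encodes target class and
lineage: ``18SrDNA_``/``5.8SrDNA_`` prefixes are 45S rDNA probes, ``5SrDNA_``
5S probes (with ``ang``/``gym``/``cranial`` lineage variants), ``Tel_``
telomere, ``Pgms`` minisatellite.  A packaged table of 26 probes covering
18S, 5.8S and 5S rDNA, the plant telomere repeat and the ginseng Pgms1
minisatellite ships with the package.

Cocktails pool all probes of one target class (optionally filtered by
lineage) under a single 5′ fluorophore; distinct cocktails mixed in one
experiment must occupy distinct emission channels.  Very-high-copy targets
(tandem rDNA arrays) can be so bright that their emission bleeds into
neighboring filters; the crosstalk guard truncates such a cocktail to the
few lowest-numbered probes instead of relying on spectral unmixing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Sequence

import pandas as pd

from .iupac_seq import DegenerateSeq
from .thermo import TmRange

__all__ = [
    "ProbeRecord",
    "Cocktail",
    "ProbeTableError",
    "packaged_table_path",
    "load_probe_table",
    "write_probe_table",
    "assemble_cocktails",
    "crosstalk_guard",
    "cocktail_to_fasta",
]

_COLUMNS = [
    "No.",
    "Probe",
    "Sequence",
    "Length",
    "Position in consensus",
    "Tm (°C)",
    "Modification",
]

#: Emission channel class of each supported fluorophore; FAM and Alexa
#: Fluor 488 are interchangeable green-channel labels.
CHANNEL_CLASS = {
    "Cy3": "red",
    "Alexa Fluor 488": "green",
    "FAM": "green",
    "ATTO425": "blue",
}


class ProbeTableError(ValueError):
    """Probe table failed validation; message names the offending row."""


@dataclass(frozen=True)
class ProbeRecord:
    """One probe-table row."""

    number: int
    name: str
    sequence: DegenerateSeq
    length: int
    position: tuple[int, int] | None  #: 1-based inclusive, None for tandem probes
    printed_tm: TmRange
    fluorophore: str
    modification_end: str = "5′"

    @property
    def target_class(self) -> str:
        """Target class derived from the probe-name prefix."""
        if self.name.startswith(("18SrDNA_", "5.8SrDNA_")):
            return "45S"
        if self.name.startswith("5SrDNA_"):
            return "5S"
        if self.name.startswith("Tel_"):
            return "telomere"
        if self.name.startswith("Pgms"):
            return "minisatellite"
        raise ValueError(f"cannot derive target class from probe name {self.name!r}")

    @property
    def lineage(self) -> str | None:
        """Lineage token of 5S variants (``ang``/``gym``/``cranial``),
        ``universal`` for UniOP probes, None otherwise."""
        parts = self.name.split("_")
        if len(parts) >= 2:
            if parts[1] in {"ang", "gym", "cranial"}:
                return parts[1]
            if parts[1] == "UniOP":
                return "universal"
        return None

    @property
    def position_index(self) -> int | None:
        """Trailing position index of the probe name (the suffix integer
        that groups lineage variants of one design position), or None."""
        tail = self.name.rsplit("_", 1)[-1]
        return int(tail) if tail.isdigit() else None

    @property
    def channel(self) -> str:
        return CHANNEL_CLASS[self.fluorophore]


@dataclass(frozen=True)
class Cocktail:
    """Pooled probes sharing one fluorophore/channel."""

    name: str
    members: tuple[ProbeRecord, ...]
    channel: str
    fluorophore: str
    note: str = ""

    def __post_init__(self):
        for m in self.members:
            if CHANNEL_CLASS[m.fluorophore] != self.channel:
                raise ValueError(
                    f"cocktail {self.name!r}: member {m.name} is on channel "
                    f"{CHANNEL_CLASS[m.fluorophore]!r}, not {self.channel!r}"
                )

    def __len__(self) -> int:
        return len(self.members)


def packaged_table_path() -> Path:
    """Path of the packaged 26-probe table."""
    return Path(resources.files("oligofish.data") / "probe_table.tsv")


def _parse_position(text: str) -> tuple[int, int] | None:
    t = str(text).strip()
    if t.lower() in {"na", "n/a", "", "nan", "none"}:
        return None
    for sep in ("…", "...", ".."):
        if sep in t:
            lo, hi = t.split(sep, 1)
            return int(lo), int(hi)
    raise ValueError(f"cannot parse position {text!r}")


def _parse_modification(text: str) -> tuple[str, str]:
    """Split a Modification cell into (end, fluorophore); a bare fluorophore
    is taken as 5′-labeled (all probes in this design are)."""
    t = str(text).strip()
    for prefix in ("5′-", "5'-", "5′", "5'"):
        if t.startswith(prefix):
            return "5′", t[len(prefix):].strip("- ")
    return "5′", t


def load_probe_table(path: str | Path | None = None) -> list[ProbeRecord]:
    """Parse a probe-table TSV (the packaged table when ``path`` is None).

    Validates that every row's Sequence is IUPAC-legal and that its length
    equals the printed Length column; a mismatch raises
    :class:`ProbeTableError` naming the row.
    """
    if path is None:
        path = packaged_table_path()
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ProbeTableError(f"{path}: missing columns {missing}")
    records = []
    for _, row in df.iterrows():
        name = row["Probe"]
        try:
            seq = DegenerateSeq(row["Sequence"])
            declared = int(row["Length"])
            if len(seq) != declared:
                raise ProbeTableError(
                    f"row {row['No.']} ({name}): sequence length {len(seq)} "
                    f"!= declared Length {declared}"
                )
            end, fluor = _parse_modification(row["Modification"])
            records.append(
                ProbeRecord(
                    number=int(row["No."]),
                    name=name,
                    sequence=seq,
                    length=declared,
                    position=_parse_position(row["Position in consensus"]),
                    printed_tm=TmRange.parse(row["Tm (°C)"]),
                    fluorophore=fluor,
                    modification_end=end,
                )
            )
        except ProbeTableError:
            raise
        except (ValueError, KeyError) as exc:
            raise ProbeTableError(f"row {row['No.']} ({name}): {exc}") from exc
    return records


def write_probe_table(records: Sequence[ProbeRecord], path: str | Path) -> None:
    """Write records back to the probe-table TSV dialect (inverse of
    :func:`load_probe_table` up to numeric formatting)."""
    rows = []
    for r in records:
        pos = "na" if r.position is None else f"{r.position[0]}…{r.position[1]}"
        mod = r.fluorophore if r.modification_end is None else f"{r.modification_end}-{r.fluorophore}"
        rows.append(
            {
                "No.": r.number,
                "Probe": r.name,
                "Sequence": str(r.sequence),
                "Length": r.length,
                "Position in consensus": pos,
                "Tm (°C)": str(r.printed_tm),
                "Modification": mod,
            }
        )
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, sep="\t", index=False)


def assemble_cocktails(
    records: Sequence[ProbeRecord],
    experiment_spec: dict,
) -> list[Cocktail]:
    """Pool probes into per-target cocktails with channel assignment.

    ``experiment_spec`` maps a target class (``"45S"``, ``"5S"``,
    ``"telomere"``, ``"minisatellite"``) to either a fluorophore name or a
    dict ``{"fluorophore": ..., "lineages": [...]}``; the lineage filter
    keeps only the named 5S lineage variants (``ang``, ``gym``, ``cranial``;
    universal probes always pass).  Two cocktails on the same emission
    channel raise ``ValueError``.
    """
    cocktails: list[Cocktail] = []
    used_channels: dict[str, str] = {}
    for target, spec in experiment_spec.items():
        if isinstance(spec, str):
            fluor, lineages = spec, None
        else:
            fluor = spec.get("fluorophore") or spec.get("channel")
            lineages = spec.get("lineages")
        if fluor not in CHANNEL_CLASS:
            raise ValueError(f"unknown fluorophore {fluor!r} for target {target!r}")
        channel = CHANNEL_CLASS[fluor]
        if channel in used_channels:
            raise ValueError(
                f"channel collision: targets {used_channels[channel]!r} and "
                f"{target!r} both assigned the {channel} channel"
            )
        used_channels[channel] = target
        members = [r for r in records if r.target_class == target]
        if lineages is not None:
            allowed = set(lineages)
            members = [
                r for r in members if r.lineage in allowed or r.lineage == "universal"
            ]
        members.sort(key=lambda r: r.number)
        # the cocktail's label is the experiment's choice, not the table's
        members = [replace(r, fluorophore=fluor) for r in members]
        cocktails.append(
            Cocktail(
                name=target,
                members=tuple(members),
                channel=channel,
                fluorophore=fluor,
            )
        )
    return cocktails


def crosstalk_guard(
    cocktails: Sequence[Cocktail],
    bright_targets: Sequence[str],
    cap: int = 4,
) -> list[Cocktail]:
    """Cap the probe count of very-high-copy (bright) targets.

    Tandem rDNA arrays carry thousands of probe binding sites; with a full
    cocktail their emission can bleed into adjacent filter channels and
    mimic colocalization.  For each cocktail named in ``bright_targets`` the
    members are truncated to the ``cap`` lowest-numbered probes; others are
    returned untouched.  The truncation is recorded in the cocktail's
    ``note`` and emitted as a ``UserWarning``.
    """
    if cap < 1:
        raise ValueError("cap must be >= 1")
    bright = set(bright_targets)
    out = []
    for c in cocktails:
        if c.name in bright and len(c.members) > cap:
            kept = tuple(sorted(c.members, key=lambda r: r.number)[:cap])
            note = (
                f"bright target: truncated from {len(c.members)} to {cap} probes "
                f"(nos. {', '.join(str(r.number) for r in kept)}) to avoid "
                f"signal crosstalk into neighboring channels"
            )
            warnings.warn(f"cocktail {c.name!r}: {note}", UserWarning, stacklevel=2)
            out.append(replace(c, members=kept, note=note))
        else:
            out.append(c)
    return out


def cocktail_to_fasta(cocktail: Cocktail, path: str | Path) -> None:
    """Export a cocktail as FASTA for synthesis ordering."""
    from .iupac_seq import write_fasta

    write_fasta(path, [(m.name, m.sequence) for m in cocktail.members])
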