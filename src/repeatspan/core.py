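"""Domain types and sequence/locus I/O.

Coordinate convention: all reference coordinates are 0-based half-open.
Locus config files may declare ``coordinate_system: 1-based`` (inclusive
start/end, as printed in most figures), in which case the conversion
happens here, at the config boundary, and nowhere else.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

READ_ALPHABET = frozenset("ACGTN")
REFERENCE_ALPHABET = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

DEFAULT_FLANK_LENGTH = 100


class RepeatSpanError(Exception):
    """Base class for repeatspan errors."""


class ValidationError(RepeatSpanError):
    """A domain object violated one of its invariants."""


class ParseError(RepeatSpanError):
    """An input file could not be parsed."""


def reverse_complement(sequence: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet.

    Applying it twice returns the input (involution).
    """
    seq = sequence.upper()
    bad = set(seq) - READ_ALPHABET
    if bad:
        raise ValidationError(f"non-nucleotide symbols in sequence: {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class LongRead:
    """A single long read: identifier, sequence, optional qualities/platform."""

    read_id: str
    sequence: str
    qualities: Sequence[int] | None = None
    platform: str | None = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if len(self.sequence) < 1:
            raise ValidationError(f"read {self.read_id!r}: empty sequence")
        bad = set(self.sequence) - READ_ALPHABET
        if bad:
            raise ValidationError(
                f"read {self.read_id!r}: invalid symbols {sorted(bad)}"
            )
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ValidationError(
                f"read {self.read_id!r}: qualities length {len(self.qualities)} "
                f"!= sequence length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def reverse_complement(self) -> "LongRead":
        quals = None if self.qualities is None else list(self.qualities)[::-1]
        return LongRead(self.read_id, reverse_complement(self.sequence), quals, self.platform)


@dataclass(frozen=True)
class RepeatLocus:
    """A target repeat locus: motif, reference span, and its two flanks.

    ``flank_up`` is the reference sequence immediately 5' of the repeat
    (its last base abuts ``repeat_start``); ``flank_down`` immediately 3'
    (its first base is at ``repeat_end``). Flanks must not contain two or
    more consecutive copies of the motif: anchoring correctness depends on
    the flanks being unambiguous against the repeat itself, so this is a
    hard validation, not a warning.
    """

    name: str
    reference_name: str
    repeat_start: int
    repeat_end: int
    motif: str
    flank_up: str
    flank_down: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "motif", self.motif.upper())
        object.__setattr__(self, "flank_up", self.flank_up.upper())
        object.__setattr__(self, "flank_down", self.flank_down.upper())
        if self.repeat_end <= self.repeat_start:
            raise ValidationError(
                f"locus {self.name!r}: repeat_end ({self.repeat_end}) must exceed "
                f"repeat_start ({self.repeat_start})"
            )
        if len(self.motif) < 1:
            raise ValidationError(f"locus {self.name!r}: empty motif")
        for label, seq in (("motif", self.motif), ("flank_up", self.flank_up), ("flank_down", self.flank_down)):
            bad = set(seq) - REFERENCE_ALPHABET
            if bad:
                raise ValidationError(
                    f"locus {self.name!r}: {label} contains invalid symbols {sorted(bad)}"
                )
        tandem = self.motif * 2
        for label, seq in (("flank_up", self.flank_up), ("flank_down", self.flank_down)):
            if tandem in seq:
                raise ValidationError(
                    f"locus {self.name!r}: {label} contains >=2 consecutive copies of "
                    f"motif {self.motif!r}; anchoring would be ambiguous"
                )

    @property
    def motif_len(self) -> int:
        return len(self.motif)

    @property
    def reference_repeat_nt(self) -> int:
        """Length of the repeat region in the reference, in nucleotides."""
        return self.repeat_end - self.repeat_start


@dataclass(frozen=True)
class BackboneSet:
    """Named identifying sequences used to bin reads by plasmid backbone."""

    entries: Mapping[str, str]

    def __post_init__(self) -> None:
        upper = {name: seq.upper() for name, seq in self.entries.items()}
        object.__setattr__(self, "entries", upper)
        names = list(upper)
        for i, a in enumerate(names):
            for b in names:
                if a != b and upper[a] in upper[b]:
                    raise ValidationError(
                        f"backbone {a!r} sequence is a substring of {b!r}; "
                        "binning would be ambiguous"
                    )


# ---------------------------------------------------------------------------
# Sequence I/O


def _infer_format(path: str | Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt.lower()
    suffix = Path(path).suffix.lower()
    if suffix in (".fq", ".fastq"):
        return "fastq"
    return "fasta"


def read_sequences(path: str | Path, format: str | None = None) -> list[LongRead]:
    """Read FASTA/FASTQ into LongReads, order preserved, uppercased.

    An empty file yields an empty list. A malformed record raises
    :class:`ParseError` naming the (0-based) record index.
    """
    fmt = _infer_format(path, format)
    if fmt not in ("fasta", "fastq"):
        raise ValueError(f"unsupported format {fmt!r}")
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    reads: list[LongRead] = []
    try:
        for index, record in enumerate(SeqIO.parse(str(path), fmt)):
            quals = record.letter_annotations.get("phred_quality")
            try:
                reads.append(LongRead(record.id, str(record.seq), quals))
            except ValidationError as exc:
                raise ParseError(f"record {index} in {path}: {exc}") from exc
    except ValueError as exc:  # Biopython parse failure
        raise ParseError(f"record {len(reads)} in {path}: {exc}") from exc
    return reads


def write_sequences(reads: Iterable[LongRead], path: str | Path, format: str | None = None) -> None:
    """Write LongReads as FASTA or 4-line FASTQ (placeholder qualities if absent)."""
    fmt = _infer_format(path, format)
    records = []
    for read in reads:
        rec = SeqRecord(Seq(read.sequence), id=read.read_id, description="")
        if fmt == "fastq":
            quals = read.qualities if read.qualities is not None else [40] * len(read)
            rec.letter_annotations["phred_quality"] = list(quals)
        records.append(rec)
    SeqIO.write(records, str(path), fmt)


def read_sam_sequences(path: str | Path) -> list[LongRead]:
    """Extract read id + sequence from SAM/BAM; alignments are recomputed internally."""
    import pysam

    reads: list[LongRead] = []
    seen: set[str] = set()
    with pysam.AlignmentFile(str(path), check_sq=False) as handle:
        for aln in handle.fetch(until_eof=True):
            if aln.is_secondary or aln.is_supplementary:
                continue
            if aln.query_name in seen or aln.query_sequence is None:
                continue
            seen.add(aln.query_name)
            seq = aln.query_sequence
            if aln.is_reverse:
                seq = reverse_complement(seq)
            reads.append(LongRead(aln.query_name, seq))
    return reads


# ---------------------------------------------------------------------------
# Config I/O


def _locus_from_mapping(cfg: Mapping, source: str = "<config>") -> RepeatLocus:
    required = ("name", "reference_name", "repeat_start", "repeat_end", "motif", "flank_up", "flank_down")
    missing = [key for key in required if key not in cfg]
    if missing:
        raise ValidationError(f"{source}: locus config missing keys {missing}")
    start = int(cfg["repeat_start"])
    end = int(cfg["repeat_end"])
    system = str(cfg.get("coordinate_system", "0-based"))
    if system == "1-based":
        # inclusive 1-based -> 0-based half-open
        start -= 1
    elif system != "0-based":
        raise ValidationError(f"{source}: unknown coordinate_system {system!r}")
    flank_length = int(cfg.get("flank_length", DEFAULT_FLANK_LENGTH))
    if flank_length < 1:
        raise ValidationError(f"{source}: flank_length must be positive")
    flank_up = str(cfg["flank_up"]).upper()
    flank_down = str(cfg["flank_down"]).upper()
    # the flank closest to the repeat is kept when trimming
    flank_up = flank_up[-flank_length:]
    flank_down = flank_down[:flank_length]
    return RepeatLocus(
        name=str(cfg["name"]),
        reference_name=str(cfg["reference_name"]),
        repeat_start=start,
        repeat_end=end,
        motif=str(cfg["motif"]),
        flank_up=flank_up,
        flank_down=flank_down,
    )


def load_locus(path: str | Path) -> RepeatLocus:
    """Load a validated RepeatLocus from a YAML config file.

    Accepts either a top-level ``locus:`` block or the locus keys at top
    level. Flank sequences are trimmed to ``flank_length`` (default 100)
    keeping the side adjacent to the repeat.
    """
    with open(path) as handle:
        data = yaml.safe_load(handle)
    if not isinstance(data, Mapping):
        raise ParseError(f"{path}: expected a mapping at top level")
    cfg = data.get("locus", data)
    if not isinstance(cfg, Mapping):
        raise ParseError(f"{path}: 'locus' must be a mapping")
    return _locus_from_mapping(cfg, source=str(path))


def load_backbones(path: str | Path) -> BackboneSet:
    """Load a BackboneSet from a YAML config (``backbones: {name: seq}``)."""
    with open(path) as handle:
        data = yaml.safe_load(handle)
    if not isinstance(data, Mapping):
        raise ParseError(f"{path}: expected a mapping at top level")
    entries = data.get("backbones", data)
    if not isinstance(entries, Mapping) or not entries:
        raise ParseError(f"{path}: 'backbones' must be a non-empty mapping")
    return BackboneSet({str(k): str(v) for k, v in entries.items()})
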