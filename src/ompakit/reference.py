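"""K-12 OmpA reference sequence and segment geometry.

The mature OmpA chain (325 residues, after cleavage of a 21-residue signal
peptide) is the coordinate system for everything in this package: allele
classification sites, surface-loop boundaries and the transmembrane strands of
both the 8-strand and the 16-strand ("large pore") topology models. All
coordinates are 1-based on the mature chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import yaml
from Bio import SeqIO

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")


class ReferenceError(ValueError):
    """Raised when reference data violates its structural invariants."""


@dataclass(frozen=True)
class SegmentDefinition:
    """One contiguous stretch of the mature chain (loop or strand)."""

    name: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    surface_exposed: bool

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ReferenceError(f"segment {self.name}: bad bounds {self.start}..{self.end}")

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class ClassificationPosition:
    position: int
    classifying: bool


@dataclass(frozen=True)
class OmpAReference:
    mature_sequence: str
    signal_peptide: str
    segments: tuple[SegmentDefinition, ...]
    classification_positions: tuple[ClassificationPosition, ...] = field(default=())

    def __post_init__(self) -> None:
        n = len(self.mature_sequence)
        if n != 325:
            raise ReferenceError(f"mature chain must be 325 residues, got {n}")
        if len(self.signal_peptide) != 21:
            raise ReferenceError("signal peptide must be 21 residues")
        bad = set(self.mature_sequence + self.signal_peptide) - AMINO_ACIDS
        if bad:
            raise ReferenceError(f"non-amino-acid characters in reference: {sorted(bad)}")
        covered: list[SegmentDefinition] = sorted(self.segments, key=lambda s: s.start)
        for prev, cur in zip(covered, covered[1:]):
            if cur.start <= prev.end:
                raise ReferenceError(f"segments {prev.name} and {cur.name} overlap")
        if covered and covered[-1].end > n:
            raise ReferenceError("segment extends past mature chain")
        for cp in self.classification_positions:
            if not 1 <= cp.position <= n:
                raise ReferenceError(f"classification position {cp.position} out of range")

    @property
    def precursor_sequence(self) -> str:
        return self.signal_peptide + self.mature_sequence

    @property
    def signal_peptide_length(self) -> int:
        return len(self.signal_peptide)

    def residue(self, position: int) -> str:
        """Residue at a 1-based mature position."""
        return self.mature_sequence[position - 1]

    def segment(self, name: str) -> SegmentDefinition:
        for seg in self.segments:
            if seg.name == name:
                return seg
        raise KeyError(name)

    def segment_sequence(self, name: str, sequence: str | None = None) -> str:
        """Slice a segment out of `sequence` (default: the reference itself)."""
        seg = self.segment(name)
        seq = self.mature_sequence if sequence is None else sequence
        return seq[seg.start - 1 : seg.end]

    def classifying_positions(self) -> tuple[int, ...]:
        return tuple(cp.position for cp in self.classification_positions if cp.classifying)

    def non_classifying_positions(self) -> tuple[int, ...]:
        return tuple(cp.position for cp in self.classification_positions if not cp.classifying)


def _data_text(filename: str) -> str:
    return resources.files("ompakit.data").joinpath(filename).read_text(encoding="utf-8")


def load_reference() -> OmpAReference:
    """Load the bundled K-12 MG1655 reference (sequence + geometry)."""
    import io

    record = next(SeqIO.parse(io.StringIO(_data_text("ompa_k12.fasta")), "fasta"))
    geom = yaml.safe_load(_data_text("reference.yaml"))
    spl = int(geom["signal_peptide_length"])
    precursor = str(record.seq)
    segments = tuple(
        SegmentDefinition(d["name"], int(d["start"]), int(d["end"]), bool(d["surface_exposed"]))
        for d in geom["segments"]
    )
    positions = tuple(
        ClassificationPosition(int(d["position"]), bool(d["classifying"]))
        for d in geom["classification_positions"]
    )
    ref = OmpAReference(
        mature_sequence=precursor[spl:],
        signal_peptide=precursor[:spl],
        segments=segments,
        classification_positions=positions,
    )
    if len(ref.mature_sequence) != int(geom["mature_length"]):
        raise ReferenceError("mature length in geometry file disagrees with FASTA")
    return ref
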