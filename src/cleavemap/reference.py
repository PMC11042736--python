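"""Reference sequences, feature annotation, and tRNA coordinate services.

Coordinates are 0-based half-open everywhere inside the package; user-facing
report writers convert to 1-based fully-closed positions.  The annotation
format is BED-like: the six standard BED columns with the score slot carrying
the feature class (``CDS``/``tRNA``/``rRNA``/``other``), and, on tRNA lines
only, two extra columns giving the transcript-relative offset of the first
anticodon nucleotide (N1) and the anticodon sequence.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq

FEATURE_CLASSES = ("CDS", "tRNA", "rRNA", "other")

#: structural numbering of the 7-nt anticodon loop; the anticodon occupies
#: loop positions 34-36 (N1-N3)
LOOP_POSITIONS = (32, 33, 34, 35, 36, 37, 38)
N1_LOOP_POSITION = 34

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class AnnotationError(ValueError):
    """Raised when sequences or annotation fail validation."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Feature:
    """An annotated genomic interval (0-based half-open, stranded)."""

    name: str
    reference_id: str
    start: int
    end: int
    strand: str
    feature_class: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise AnnotationError(
                f"feature {self.name!r}: start {self.start} >= end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"feature {self.name!r}: bad strand {self.strand!r}")
        if self.feature_class not in FEATURE_CLASSES:
            raise AnnotationError(
                f"feature {self.name!r}: unknown class {self.feature_class!r} "
                f"(expected one of {FEATURE_CLASSES})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def transcript_to_genomic(self, offset: int) -> int:
        """Map a transcript-relative offset (0 = the 5' base) to a genomic position."""
        if self.strand == "+":
            return self.start + offset
        return self.end - 1 - offset

    @property
    def five_prime_pos(self) -> int:
        return self.transcript_to_genomic(0)


@dataclass(frozen=True)
class AnticodonSpec:
    """Location of the anticodon within a tRNA gene.

    ``n1_offset`` is the transcript-relative (0-based) offset of the first
    anticodon nucleotide; the surrounding anticodon loop spans the seven
    offsets ``n1_offset - 2 .. n1_offset + 4`` (structural positions 32-38).
    """

    anticodon_seq: str
    n1_offset: int

    def __post_init__(self) -> None:
        if len(self.anticodon_seq) != 3:
            raise AnnotationError(
                f"anticodon must be 3 nt, got {self.anticodon_seq!r}"
            )
        if self.n1_offset < 2:
            raise AnnotationError("anticodon N1 offset must leave room for the loop")

    @property
    def loop_offsets(self) -> tuple[int, ...]:
        return tuple(self.n1_offset + d for d in range(-2, 5))

    @property
    def anticodon_offsets(self) -> tuple[int, int, int]:
        return (self.n1_offset, self.n1_offset + 1, self.n1_offset + 2)

    def loop_offset(self, loop_position: int) -> int:
        """Transcript offset of a structural loop position (32-38)."""
        if loop_position not in LOOP_POSITIONS:
            raise AnnotationError(f"loop position {loop_position} outside 32-38")
        return self.n1_offset + (loop_position - N1_LOOP_POSITION)


@dataclass
class GenomeBundle:
    """Reference sequences plus (optionally) features and a tRNA index."""

    sequences: dict[str, str]
    features: list[Feature] = field(default_factory=list)
    trna_index: dict[str, AnticodonSpec] = field(default_factory=dict)

    def feature_sequence(self, feature: Feature) -> str:
        """Transcript-sense (5'->3') sequence of a feature."""
        raw = self.sequences[feature.reference_id][feature.start : feature.end]
        return raw if feature.strand == "+" else reverse_complement(raw)

    def trna_features(self) -> list[Feature]:
        return [f for f in self.features if f.feature_class == "tRNA"]

    def get_feature(self, name: str) -> Feature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def validate(self) -> None:
        for f in self.features:
            if f.reference_id not in self.sequences:
                raise AnnotationError(
                    f"feature {f.name!r}: unknown reference {f.reference_id!r}"
                )
            if f.end > len(self.sequences[f.reference_id]):
                raise AnnotationError(
                    f"feature {f.name!r}: interval [{f.start}, {f.end}) exceeds "
                    f"length {len(self.sequences[f.reference_id])} of "
                    f"{f.reference_id!r}"
                )
        for f in self.trna_features():
            spec = self.trna_index.get(f.name)
            if spec is None:
                raise AnnotationError(f"tRNA {f.name!r} lacks an anticodon spec")
            seq = self.feature_sequence(f)
            if spec.loop_offsets[-1] >= len(seq):
                raise AnnotationError(
                    f"tRNA {f.name!r}: anticodon loop exceeds gene length"
                )
            found = seq[spec.n1_offset : spec.n1_offset + 3]
            if found != spec.anticodon_seq:
                raise AnnotationError(
                    f"tRNA {f.name!r}: declared anticodon {spec.anticodon_seq!r} "
                    f"but gene sequence has {found!r} at offset {spec.n1_offset}"
                )


def load_genome(fasta_path: str | os.PathLike) -> GenomeBundle:
    """Read reference sequences from FASTA into a :class:`GenomeBundle`.

    Sequences are uppercased and U is converted to T.  Duplicate record ids
    and empty files are errors.
    """
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        if record.id in sequences:
            raise AnnotationError(f"duplicate FASTA record id {record.id!r}")
        sequences[record.id] = str(record.seq).upper().replace("U", "T")
    if not sequences:
        raise AnnotationError(f"no FASTA records found in {fasta_path}")
    return GenomeBundle(sequences=sequences)


def load_annotation(bed_path: str | os.PathLike, genome: GenomeBundle) -> list[Feature]:
    """Parse the BED-like annotation, validate against the genome, and attach it.

    Returns the feature list; as a side effect ``genome.features`` and
    ``genome.trna_index`` are populated.  tRNA anticodons are cross-checked
    against the genome sequence (declared as RNA or DNA; U is accepted).
    """
    features: list[Feature] = []
    trna_index: dict[str, AnticodonSpec] = {}
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 6:
                raise AnnotationError(
                    f"{bed_path}:{lineno}: expected >=6 tab-separated columns"
                )
            chrom, start, end, name, fclass, strand = cols[:6]
            feature = Feature(
                name=name,
                reference_id=chrom,
                start=int(start),
                end=int(end),
                strand=strand,
                feature_class=fclass,
            )
            if feature.feature_class == "tRNA":
                if len(cols) < 8:
                    raise AnnotationError(
                        f"{bed_path}:{lineno}: tRNA line {name!r} needs anticodon "
                        "offset and sequence columns"
                    )
                anticodon = cols[7].upper().replace("U", "T")
                trna_index[name] = AnticodonSpec(
                    anticodon_seq=anticodon, n1_offset=int(cols[6])
                )
            features.append(feature)
    genome.features = features
    genome.trna_index = trna_index
    genome.validate()
    return features


def write_annotation(genome: GenomeBundle, bed_path: str | os.PathLike) -> None:
    """Write the attached annotation back out in the package's BED-like format."""
    with open(bed_path, "w") as fh:
        for f in genome.features:
            cols = [f.reference_id, str(f.start), str(f.end), f.name,
                    f.feature_class, f.strand]
            if f.feature_class == "tRNA":
                spec = genome.trna_index[f.name]
                cols += [str(spec.n1_offset), spec.anticodon_seq]
            fh.write("\t".join(cols) + "\n")


def write_genome(genome: GenomeBundle, fasta_path: str | os.PathLike,
                 width: int = 70) -> None:
    with open(fasta_path, "w") as fh:
        for ref_id in genome.sequences:
            fh.write(f">{ref_id}\n")
            seq = genome.sequences[ref_id]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def collapse_identical_trnas(genome: GenomeBundle) -> dict[str, str]:
    """Group tRNA genes with byte-identical (transcript-sense) sequences.

    Multi-copy tRNAs in bacteria frequently have identical gene sequences;
    for transcript-level set comparisons such copies are indistinguishable
    and are merged under one group name formed from the longest common name
    prefix plus the lexicographically sorted distinguishing suffixes
    (glnU + glnW -> glnUW).  Singletons map to themselves.
    """
    by_seq: dict[str, list[str]] = {}
    for f in genome.trna_features():
        by_seq.setdefault(genome.feature_sequence(f), []).append(f.name)
    mapping: dict[str, str] = {}
    for names in by_seq.values():
        names = sorted(names)
        if len(names) == 1:
            mapping[names[0]] = names[0]
            continue
        prefix = os.path.commonprefix(names)
        suffixes = sorted(n[len(prefix) :] for n in names)
        group = prefix + "".join(suffixes)
        for n in names:
            mapping[n] = group
    return mapping
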