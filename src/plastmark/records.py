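"""Domain containers: annotated plastome records and region alignments.

Coordinates are 0-based, half-open throughout; the GenBank reader converts
from the 1-based inclusive convention at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seq import array_to_seq, seq_to_array

FEATURE_KINDS = ("gene", "CDS", "tRNA", "rRNA")


@dataclass
class Feature:
    """One annotated feature with possibly spliced (multi-interval) location."""

    name: str
    kind: str
    strand: str
    intervals: list[tuple[int, int]]
    qualifiers: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.intervals:
            raise ValueError(f"feature {self.name!r} has no intervals")
        for start, end in self.intervals:
            if start >= end:
                raise ValueError(
                    f"feature {self.name!r}: empty interval [{start},{end})"
                )

    @property
    def span(self) -> tuple[int, int]:
        """Overall [start, end) footprint on the + strand."""
        return self.intervals[0][0], self.intervals[-1][1]

    def length(self) -> int:
        return sum(e - s for s, e in self.intervals)


@dataclass
class PlastomeRecord:
    """One annotated (circular) plastid genome."""

    accession: str
    sequence: str
    circular: bool = True
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty genome sequence")
        n = len(self.sequence)
        for feat in self.features:
            for start, end in feat.intervals:
                if not (0 <= start < end <= n):
                    raise ValueError(
                        f"feature {feat.name!r} interval [{start},{end}) "
                        f"outside genome of length {n}"
                    )

    def __len__(self) -> int:
        return len(self.sequence)

    def genes(self) -> list[Feature]:
        return [f for f in self.features if f.kind == "gene"]

    def feature_sequence(self, feat: Feature) -> str:
        """Spliced feature sequence, reverse-complemented on the - strand."""
        from ._seq import revcomp

        parts = [self.sequence[s:e] for s, e in feat.intervals]
        seq = "".join(parts)
        return revcomp(seq) if feat.strand == "-" else seq


@dataclass
class RegionSequence:
    """One gene or intergenic-spacer sequence from one taxon.

    IGS regions are named by their flanking genes in genome order,
    e.g. ``"rpoB-trnC"``.
    """

    region_name: str
    region_kind: str  # "gene" or "IGS"
    taxon: str
    sequence: str


class RegionAlignment:
    """Aligned matrix (taxa x columns) for one named region.

    Rows may contain A, C, G, T, N and the gap character ``-``.
    """

    def __init__(
        self,
        region_name: str,
        region_kind: str,
        taxa: list[str],
        matrix: np.ndarray,
    ) -> None:
        matrix = np.asarray(matrix, dtype="U1")
        if matrix.ndim != 2:
            raise ValueError("alignment matrix must be 2-D")
        if len(taxa) != matrix.shape[0]:
            raise ValueError("taxa list does not match matrix rows")
        if len(set(taxa)) != len(taxa):
            raise ValueError("duplicate taxon names in alignment")
        self.region_name = region_name
        self.region_kind = region_kind
        self.taxa = list(taxa)
        self.matrix = matrix

    @classmethod
    def from_sequences(
        cls,
        region_name: str,
        region_kind: str,
        named_seqs: list[tuple[str, str]],
    ) -> "RegionAlignment":
        lengths = {len(s) for _, s in named_seqs}
        if len(lengths) > 1:
            bad = sorted({name for name, s in named_seqs})
            raise ValueError(
                f"ragged alignment {region_name!r}: row lengths {sorted(lengths)} "
                f"across taxa {bad}"
            )
        taxa = [name for name, _ in named_seqs]
        matrix = np.stack([seq_to_array(s.upper()) for _, s in named_seqs])
        return cls(region_name, region_kind, taxa, matrix)

    @property
    def n_taxa(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    def row(self, taxon: str) -> str:
        return array_to_seq(self.matrix[self.taxa.index(taxon)])

    def subset_columns(self, start: int, end: int) -> "RegionAlignment":
        return RegionAlignment(
            self.region_name, self.region_kind, self.taxa, self.matrix[:, start:end]
        )

    def reorder(self, taxa: list[str]) -> "RegionAlignment":
        idx = [self.taxa.index(t) for t in taxa]
        return RegionAlignment(
            self.region_name, self.region_kind, list(taxa), self.matrix[idx]
        )

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"RegionAlignment({self.region_name!r}, {self.region_kind!r}, "
            f"{self.n_taxa} taxa x {self.n_columns} columns)"
        )


def concatenate_alignments(
    alignments: list[RegionAlignment], name: str = "concat"
) -> tuple[RegionAlignment, dict[str, tuple[int, int]]]:
    """Column-wise concatenation over a shared taxon set.

    Returns the concatenated alignment and a map region -> [start, end)
    column block, so per-region structure survives concatenation.
    """
    if not alignments:
        raise ValueError("nothing to concatenate")
    taxa = alignments[0].taxa
    blocks = []
    region_map: dict[str, tuple[int, int]] = {}
    offset = 0
    for aln in alignments:
        if set(aln.taxa) != set(taxa):
            raise ValueError(
                f"taxon set mismatch in region {aln.region_name!r}: "
                f"{sorted(set(aln.taxa) ^ set(taxa))}"
            )
        blocks.append(aln.reorder(taxa).matrix)
        region_map[aln.region_name] = (offset, offset + aln.n_columns)
        offset += aln.n_columns
    combined = RegionAlignment(name, "concat", taxa, np.concatenate(blocks, axis=1))
    return combined, region_map
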