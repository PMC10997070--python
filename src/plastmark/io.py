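"""Readers and writers for GenBank, FASTA and newick, plus basic
sequence utilities used everywhere in the pipeline.

GenBank parsing is delegated to Biopython; this module adds the
validation and the coordinate bookkeeping the pipeline relies on
(0-based half-open intervals, rejection of origin-wrapping features,
ambiguity-code sanitization).
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from ._seq import revcomp, sanitize
from .records import Feature, PlastomeRecord, RegionAlignment, RegionSequence
from .trees import PhyloTree

logger = logging.getLogger(__name__)

_KIND_MAP = {"gene": "gene", "CDS": "CDS", "tRNA": "tRNA", "rRNA": "rRNA"}


class GenBankParseError(ValueError):
    pass


# --------------------------------------------------------------------- GenBank


def _declared_length(path: Path) -> int | None:
    with open(path) as fh:
        for line in fh:
            if line.startswith("LOCUS"):
                tokens = line.split()
                for i, tok in enumerate(tokens):
                    if tok == "bp" and i > 0 and tokens[i - 1].isdigit():
                        return int(tokens[i - 1])
                return None
    return None


def _feature_name(bio_feat) -> str:
    for key in ("gene", "locus_tag", "product"):
        if key in bio_feat.qualifiers:
            return bio_feat.qualifiers[key][0]
    return bio_feat.type


def read_genbank(path: str | Path) -> PlastomeRecord:
    """Parse a GenBank flat file into a :class:`PlastomeRecord`.

    The sequence is uppercased and ambiguity codes other than N are
    mapped to N (the replacement count is logged).  Simple,
    ``complement(...)``, ``join(...)`` and ``complement(join(...))``
    locations become ordered 0-based half-open intervals.
    """
    path = Path(path)
    try:
        bio_record = SeqIO.read(path, "genbank")
    except ValueError as exc:
        raise GenBankParseError(f"{path}: {exc}") from exc

    declared = _declared_length(path)
    actual = len(bio_record.seq)
    if declared is not None and declared != actual:
        raise GenBankParseError(
            f"{path}: LOCUS declares {declared} bp but ORIGIN holds {actual} bases"
        )

    sequence, n_replaced = sanitize(str(bio_record.seq))
    if n_replaced:
        logger.info(
            "%s: mapped %d ambiguity bases to N", bio_record.id, n_replaced
        )

    n = len(sequence)
    features: list[Feature] = []
    for bio_feat in bio_record.features:
        kind = _KIND_MAP.get(bio_feat.type)
        if kind is None:
            continue
        loc = bio_feat.location
        parts = loc.parts if isinstance(loc, CompoundLocation) else [loc]
        strands = {p.strand for p in parts}
        if len(strands) != 1:
            raise GenBankParseError(
                f"{path}: feature {_feature_name(bio_feat)!r} mixes strands "
                "(unsupported location operator)"
            )
        strand = "-" if strands.pop() == -1 else "+"
        intervals = [(int(p.start), int(p.end)) for p in parts]
        # reject features wrapping the origin of the linearized circle
        file_order = sorted(intervals) if strand == "+" else intervals
        spans_end = any(e == n for _, e in intervals)
        spans_start = any(s == 0 for s, _ in intervals)
        if len(intervals) > 1 and spans_end and spans_start:
            raise GenBankParseError(
                f"{path}: feature {_feature_name(bio_feat)!r} wraps the "
                "sequence origin; rotate the record so no feature crosses "
                "position 0"
            )
        intervals.sort()
        features.append(
            Feature(
                name=_feature_name(bio_feat),
                kind=kind,
                strand=strand,
                intervals=intervals,
                qualifiers={k: v[0] for k, v in bio_feat.qualifiers.items()},
            )
        )

    circular = "circular" in bio_record.annotations.get("topology", "circular")
    return PlastomeRecord(
        accession=bio_record.id or path.stem,
        sequence=sequence,
        circular=circular,
        features=features,
    )


def write_genbank(record: PlastomeRecord, path: str | Path) -> None:
    bio_features = []
    for feat in record.features:
        strand = -1 if feat.strand == "-" else 1
        locs = [SimpleLocation(s, e, strand) for s, e in feat.intervals]
        location = locs[0] if len(locs) == 1 else CompoundLocation(locs)
        bio_features.append(
            SeqFeature(location, type=feat.kind, qualifiers={"gene": [feat.name]})
        )
    bio_record = SeqRecord(
        Seq(record.sequence),
        id=record.accession,
        name=record.accession[:16].replace(" ", "_"),
        description="",
        features=bio_features,
        annotations={
            "molecule_type": "DNA",
            "topology": "circular" if record.circular else "linear",
        },
    )
    SeqIO.write(bio_record, str(path), "genbank")


# ------------------------------------------------------------------ utilities


def gc_content(sequence: str) -> float:
    """(G+C) / (A+C+G+T); N and gaps are excluded from the denominator."""
    seq = sequence.upper()
    counts = {b: seq.count(b) for b in "ACGT"}
    denom = sum(counts.values())
    if denom == 0:
        raise ValueError("GC content undefined: no unambiguous bases")
    return (counts["G"] + counts["C"]) / denom


def extract_regions(record: PlastomeRecord) -> list[RegionSequence]:
    """Per-gene and per-IGS sequences of one genome.

    Gene sequences are spliced and reverse-complemented on the -
    strand.  IGS regions are the + strand gaps between consecutive gene
    spans, named ``"leftGene-rightGene"``; zero-length gaps are omitted
    and gaps swallowed by overlapping genes are skipped with a logged
    warning.
    """
    genes = sorted(record.genes(), key=lambda f: f.span)
    if not genes:
        raise ValueError(f"{record.accession}: no gene features")
    out: list[RegionSequence] = []
    for i, gene in enumerate(genes):
        out.append(
            RegionSequence(
                region_name=gene.name,
                region_kind="gene",
                taxon=record.accession,
                sequence=record.feature_sequence(gene),
            )
        )
        if i + 1 < len(genes):
            nxt = genes[i + 1]
            gap_start, gap_end = gene.span[1], nxt.span[0]
            if gap_end < gap_start:
                logger.warning(
                    "%s: genes %s and %s overlap; IGS omitted",
                    record.accession,
                    gene.name,
                    nxt.name,
                )
                continue
            if gap_end == gap_start:
                continue
            out.append(
                RegionSequence(
                    region_name=f"{gene.name}-{nxt.name}",
                    region_kind="IGS",
                    taxon=record.accession,
                    sequence=record.sequence[gap_start:gap_end],
                )
            )
    return out


# -------------------------------------------------------------------- FASTA


def read_fasta_alignment(
    path: str | Path, region_name: str | None = None, region_kind: str = "gene"
) -> RegionAlignment:
    path = Path(path)
    named = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(path, "fasta")]
    if not named:
        raise ValueError(f"{path}: empty FASTA")
    return RegionAlignment.from_sequences(
        region_name or path.stem, region_kind, named
    )


def write_fasta_alignment(
    alignment: RegionAlignment, path: str | Path, width: int = 80
) -> None:
    with open(path, "w") as fh:
        for taxon in alignment.taxa:
            seq = alignment.row(taxon)
            fh.write(f">{taxon}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_fasta(named_seqs: list[tuple[str, str]], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in named_seqs:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(Path(path), "fasta")]


# -------------------------------------------------------------------- newick


def read_newick(path: str | Path) -> PhyloTree:
    return PhyloTree.from_newick(Path(path).read_text())


def write_newick(
    tree: PhyloTree, path: str | Path, include_support: bool = False
) -> None:
    Path(path).write_text(tree.to_newick(include_support=include_support) + "\n")


# --------------------------------------------------------------- region TSV


def write_region_table(regions: list[RegionSequence], path: str | Path) -> None:
    rows = [
        {
            "region_name": r.region_name,
            "kind": r.region_kind,
            "taxon": r.taxon,
            "length": len(r.sequence),
        }
        for r in regions
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
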