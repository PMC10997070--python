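"""Codon counting and relative synonymous codon usage (RSCU) over
protein-coding genes, under the bacterial/plastid genetic code
(translation table 11).

RSCU(c) = count(c) / mean count of c's synonymous family; a value of 1
means the codon is used exactly as often as expected when all synonyms
are interchangeable.  Stop codons are excluded from RSCU and reported
separately, following the CodonW convention.
"""

from __future__ import annotations

import itertools
import logging
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd
from Bio.Data import CodonTable

logger = logging.getLogger(__name__)

_TABLE = CodonTable.unambiguous_dna_by_id[11]

ALL_CODONS = ["".join(c) for c in itertools.product("ACGT", repeat=3)]
STOP_CODONS = set(_TABLE.stop_codons)
CODON_TO_AA = dict(_TABLE.forward_table)  # sense codons only

#: amino acid -> synonymous codon family (table 11)
SYNONYM_FAMILIES: dict[str, list[str]] = {}
for codon, aa in CODON_TO_AA.items():
    SYNONYM_FAMILIES.setdefault(aa, []).append(codon)
for fam in SYNONYM_FAMILIES.values():
    fam.sort()

assert len(ALL_CODONS) == 64


@dataclass
class CodonUsageTable:
    counts: dict[str, int]
    rscu: dict[str, float | None] = field(default_factory=dict)
    n_genes: int = 0
    total_codons: int = 0
    stop_counts: dict[str, int] = field(default_factory=dict)
    qc: dict[str, list[str]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for codon in ALL_CODONS:
            aa = CODON_TO_AA.get(codon, "*")
            rows.append(
                {
                    "codon": codon,
                    "amino_acid": aa,
                    "count": self.counts.get(codon, 0),
                    "rscu": self.rscu.get(codon),
                }
            )
        return pd.DataFrame(rows)

    def ending_composition(self) -> dict[str, float]:
        """Fraction of counted codons ending in each base (sums to 1)."""
        totals = Counter()
        for codon, count in self.counts.items():
            totals[codon[2]] += count
        grand = sum(totals.values())
        return {b: totals.get(b, 0) / grand for b in "ACGT"} if grand else {}


def codon_counts(
    cds_seqs: list[str] | list[tuple[str, str]]
) -> CodonUsageTable:
    """Tally codons over a CDS set.

    Accepts bare sequences or (name, sequence) pairs.  Lengths not
    divisible by 3 are truncated with a per-gene warning; terminal stop
    codons are excluded from counts; internal stops are warned about
    but the gene is retained.  Codons containing N are skipped.
    """
    named = [
        seq if isinstance(seq, tuple) else (f"cds{i+1}", seq)
        for i, seq in enumerate(cds_seqs)
    ]
    counts: Counter[str] = Counter()
    stop_counts: Counter[str] = Counter()
    qc: dict[str, list[str]] = {"truncated": [], "internal_stop": []}
    for name, seq in named:
        seq = seq.upper()
        if len(seq) % 3:
            logger.warning(
                "%s: length %d not divisible by 3; trailing %d bases dropped",
                name,
                len(seq),
                len(seq) % 3,
            )
            qc["truncated"].append(name)
            seq = seq[: len(seq) - len(seq) % 3]
        codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
        if codons and codons[-1] in STOP_CODONS:
            stop_counts[codons[-1]] += 1
            codons = codons[:-1]
        internal_stops = [c for c in codons if c in STOP_CODONS]
        if internal_stops:
            logger.warning(
                "%s: %d internal stop codon(s); gene retained",
                name,
                len(internal_stops),
            )
            qc["internal_stop"].append(name)
        counts.update(c for c in codons if set(c) <= set("ACGT"))
    return CodonUsageTable(
        counts=dict(counts),
        n_genes=len(named),
        total_codons=sum(counts.values()),
        stop_counts=dict(stop_counts),
        qc=qc,
    )


def rscu(table: CodonUsageTable) -> CodonUsageTable:
    """Fill in RSCU values; families never observed get None."""
    values: dict[str, float | None] = {}
    for aa, family in SYNONYM_FAMILIES.items():
        family_total = sum(table.counts.get(c, 0) for c in family)
        if family_total == 0:
            for c in family:
                values[c] = None
            continue
        mean = family_total / len(family)
        for c in family:
            values[c] = table.counts.get(c, 0) / mean
    table.rscu = values
    return table


def codon_usage(cds_seqs) -> CodonUsageTable:
    """Counts plus RSCU in one call."""
    return rscu(codon_counts(cds_seqs))


def start_codon_summary(
    named_cds: list[tuple[str, str]]
) -> tuple[dict[str, str], Counter]:
    """Initiator codon per gene and the histogram over the set."""
    initiators = {
        name: seq[:3].upper() for name, seq in named_cds if len(seq) >= 3
    }
    return initiators, Counter(initiators.values())
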