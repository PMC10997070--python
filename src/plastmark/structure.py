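"""Plastome structure: quadripartite partitioning, IR-junction reports,
microsatellite (SSR) scanning and dispersed-repeat detection.

All scanners treat the genome as the deposited linear string; the
quadripartite finder alone works circularly (via sequence doubling) so
a genome rotated across an IR is still partitioned correctly.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._seq import revcomp
from .records import PlastomeRecord

logger = logging.getLogger(__name__)

DEFAULT_SSR_THRESHOLDS = {1: 10, 2: 5, 3: 4, 4: 3, 5: 3, 6: 3}


class NoQuadripartiteStructureError(ValueError):
    pass


class AmbiguousInvertedRepeatError(ValueError):
    pass


# ------------------------------------------------------------- quadripartite


@dataclass
class QuadripartitePartition:
    """LSC/SSC/IR intervals of one circular genome.

    Intervals are (start, end) with end possibly exceeding the genome
    length to denote wrapping past the origin; junction positions are
    reduced modulo the genome length.  JLB = LSC/IRb, JSB = IRb/SSC,
    JSA = SSC/IRa, JLA = IRa/LSC.
    """

    genome_length: int
    lsc: tuple[int, int]
    irb: tuple[int, int]
    ssc: tuple[int, int]
    ira: tuple[int, int]

    @property
    def junctions(self) -> dict[str, int]:
        n = self.genome_length
        return {
            "JLB": self.irb[0] % n,
            "JSB": self.irb[1] % n,
            "JSA": self.ira[0] % n,
            "JLA": self.ira[1] % n,
        }

    def lengths(self) -> dict[str, int]:
        return {
            "LSC": self.lsc[1] - self.lsc[0],
            "SSC": self.ssc[1] - self.ssc[0],
            "IRa": self.ira[1] - self.ira[0],
            "IRb": self.irb[1] - self.irb[0],
        }


def circular_slice(sequence: str, start: int, end: int) -> str:
    """Slice [start, end) of a circular sequence (end may exceed len)."""
    n = len(sequence)
    start %= n
    length = end - start if end >= start else end + n - start
    doubled = sequence + sequence
    return doubled[start : start + length]


def _maximal_rc_matches(s: str, min_len: int) -> list[tuple[int, int, int]]:
    """Maximal exact reverse-complement repeat pairs of a circular
    sequence, as (pos1, pos2, length) with positions modulo len(s)."""
    n = len(s)
    big = s + s
    rc_big = revcomp(big)
    m = len(big)
    k = min(64, min_len)
    stride = max(1, min_len - k + 1)
    index: dict[str, list[int]] = defaultdict(list)
    for x in range(m - k + 1):
        index[rc_big[x : x + k]].append(x)

    seen_runs: set[tuple[int, int]] = set()
    pairs: dict[tuple[int, int], int] = {}
    for a in range(0, m - k + 1, stride):
        for x in index.get(big[a : a + k], ()):
            d = x - a
            lo = a
            while lo > 0 and lo - 1 + d >= 0 and big[lo - 1] == rc_big[lo - 1 + d]:
                lo -= 1
            hi = a + k
            while hi < m and hi + d < m and big[hi] == rc_big[hi + d]:
                hi += 1
            if (d, lo) in seen_runs:
                continue
            seen_runs.add((d, lo))
            length = hi - lo
            if length < min_len or length > n:
                continue
            b = 2 * n - (lo + d) - length
            p1, p2 = sorted((lo % n, b % n))
            # keep circularly disjoint pairs only
            if (p2 - p1) % n < length or (p1 - p2) % n < length:
                continue
            key = (p1, p2)
            if pairs.get(key, 0) < length:
                pairs[key] = length
    return [(p1, p2, length) for (p1, p2), length in pairs.items()]


def find_quadripartite(
    record: PlastomeRecord | str, min_ir_len: int = 1000
) -> QuadripartitePartition:
    """Locate the quadripartite structure of a circular plastome.

    Finds the longest pair of disjoint maximal reverse-complement exact
    repeats of at least ``min_ir_len`` (the two IR copies), labels the
    longer single-copy arc LSC, and calls IRb the copy that follows the
    LSC in deposited orientation.
    """
    seq = record.sequence if isinstance(record, PlastomeRecord) else record
    seq = seq.upper()
    n = len(seq)
    matches = _maximal_rc_matches(seq, min_ir_len)
    if not matches:
        raise NoQuadripartiteStructureError(
            f"no inverted repeat of >= {min_ir_len} bp found: "
            "no quadripartite structure"
        )
    top_len = max(length for _, _, length in matches)
    top = [mt for mt in matches if mt[2] == top_len]
    if len(top) > 1:
        raise AmbiguousInvertedRepeatError(
            f"{len(top)} equally long candidate IR pairs of {top_len} bp: "
            + "; ".join(f"({p1},{p2})" for p1, p2, _ in top)
        )
    p1, p2, length = top[0]
    arc1 = (p2 - (p1 + length)) % n  # between copy1 end and copy2 start
    arc2 = (p1 - (p2 + length)) % n  # between copy2 end and copy1 start
    if arc1 >= arc2:
        # arc1 is LSC, so the copy at p2 follows it: IRb at p2
        lsc_start, lsc_len = (p1 + length) % n, arc1
        ssc_start, ssc_len = (p2 + length) % n, arc2
        irb_start, ira_start = p2, p1
    else:
        lsc_start, lsc_len = (p2 + length) % n, arc2
        ssc_start, ssc_len = (p1 + length) % n, arc1
        irb_start, ira_start = p1, p2
    return QuadripartitePartition(
        genome_length=n,
        lsc=(lsc_start, lsc_start + lsc_len),
        irb=(irb_start, irb_start + length),
        ssc=(ssc_start, ssc_start + ssc_len),
        ira=(ira_start, ira_start + length),
    )


# ---------------------------------------------------------- junction report


def junction_report(
    records_and_partitions: list[tuple[PlastomeRecord, QuadripartitePartition]],
    max_distance: int = 5000,
) -> pd.DataFrame:
    """Nearest gene and its distance for each of the four IR junctions.

    ``distance`` is the gap (bp) from the nearest gene edge to the
    junction; a gene containing the junction gets the negative
    within-gene offset from the nearer edge and ``overlap=True``.
    Junctions with no gene within ``max_distance`` are reported NA.
    """
    rows = []
    for record, part in records_and_partitions:
        n = part.genome_length
        for junction, pos in part.junctions.items():
            best: tuple[int, str, bool] | None = None
            for gene in record.genes():
                start, end = gene.span
                if start < pos < end:
                    offset = min(pos - start, end - pos)
                    cand = (-offset, gene.name, True)
                else:
                    dist = min((pos - end) % n, (start - pos) % n)
                    cand = (dist, gene.name, False)
                if best is None or abs(cand[0]) < abs(best[0]):
                    best = cand
            if best is None or abs(best[0]) > max_distance:
                rows.append(
                    {
                        "accession": record.accession,
                        "junction": junction,
                        "position": pos,
                        "gene": None,
                        "distance": float("nan"),
                        "overlap": False,
                    }
                )
            else:
                rows.append(
                    {
                        "accession": record.accession,
                        "junction": junction,
                        "position": pos,
                        "gene": best[1],
                        "distance": best[0],
                        "overlap": best[2],
                    }
                )
    return pd.DataFrame(rows)


# -------------------------------------------------------------------- SSRs


@dataclass
class SSRRecord:
    motif: str
    unit_len: int
    n_repeats: int
    interval: tuple[int, int]
    compound: bool = False


def _is_primitive(motif: str) -> bool:
    u = len(motif)
    for p in range(1, u):
        if u % p == 0 and motif == motif[:p] * (u // p):
            return False
    return True


def scan_ssrs(
    sequence: str,
    thresholds: dict[int, int] | None = None,
    compound_gap: int = 100,
) -> list[SSRRecord]:
    """Maximal perfect tandem repeats of 1-6 bp motifs.

    A repeat qualifies when its full-unit count reaches the per-unit
    minimum (MISA-style thresholds).  Motifs that are repetitions of a
    shorter motif are reported at the shorter unit size only.  Two SSRs
    whose gap is at most ``compound_gap`` bases are flagged compound.
    """
    thresholds = thresholds or DEFAULT_SSR_THRESHOLDS
    s = sequence.upper()
    n = len(s)
    arr = np.frombuffer(s.encode("ascii"), dtype="S1")
    valid = np.isin(arr, [b"A", b"C", b"G", b"T"])
    records: list[SSRRecord] = []
    for u, min_reps in sorted(thresholds.items()):
        if u < 1 or u > 6:
            raise ValueError("SSR unit sizes must be 1-6")
        if n < u * min_reps:
            continue
        periodic = (arr[:-u] == arr[u:]) & valid[:-u] & valid[u:]
        # maximal runs of periodicity
        padded = np.concatenate(([False], periodic, [False]))
        edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
        for start, stop in zip(edges[::2], edges[1::2]):
            tract_len = (stop - start) + u  # periodic span plus one unit
            count = tract_len // u
            if count < min_reps:
                continue
            motif = s[start : start + u]
            if not _is_primitive(motif):
                continue
            records.append(
                SSRRecord(
                    motif=motif,
                    unit_len=u,
                    n_repeats=count,
                    interval=(int(start), int(start + u * count)),
                )
            )
    records.sort(key=lambda r: (r.interval, r.unit_len))
    for prev, nxt in zip(records, records[1:]):
        if nxt.interval[0] - prev.interval[1] <= compound_gap:
            prev.compound = True
            nxt.compound = True
    return records


def ssr_summary(records: list[SSRRecord]) -> dict:
    """Counts by unit size (1..6), total, and the compound count."""
    out = {u: 0 for u in range(1, 7)}
    for rec in records:
        out[rec.unit_len] += 1
    return {
        "by_unit": out,
        "total": len(records),
        "compound": sum(1 for r in records if r.compound),
    }


# --------------------------------------------------------- dispersed repeats


@dataclass(frozen=True)
class RepeatPair:
    kind: str  # forward | palindromic | reverse | complement
    pos1: int
    pos2: int
    length: int
    mismatches: int

    @property
    def identity(self) -> float:
        return 1.0 - self.mismatches / self.length


_COMP_ONLY = str.maketrans("ACGTN", "TGCAN")


def _second_position(kind: str, x: int, length: int, n: int) -> int:
    # map a window start in the transformed sequence back to genome coords
    if kind in ("palindromic", "reverse"):
        return n - x - length
    return x


def _maximal_windows_around_seed(
    s: str, t: str, a: int, x: int, k: int, max_mismatch: int
) -> list[tuple[int, int, int]]:
    """All maximal <=max_mismatch windows on diagonal x-a containing the
    exact seed s[a:a+k] == t[x:x+x+k]; returns (lo, hi, n_mismatch) in
    s-coordinates."""
    d = x - a
    limit_lo = max(0, -d)
    limit_hi = min(len(s), len(t) - d)
    left_mm: list[int] = []
    pos = a - 1
    while pos >= limit_lo and len(left_mm) <= max_mismatch:
        if s[pos] != t[pos + d]:
            left_mm.append(pos)
        pos -= 1
    right_mm: list[int] = []
    pos = a + k
    while pos < limit_hi and len(right_mm) <= max_mismatch:
        if s[pos] != t[pos + d]:
            right_mm.append(pos)
        pos += 1
    out = []
    for i in range(max_mismatch + 1):
        lo = left_mm[i] + 1 if i < len(left_mm) else limit_lo
        j = max_mismatch - i
        hi = right_mm[j] if j < len(right_mm) else limit_hi
        used = min(i, len(left_mm)) + min(j, len(right_mm))
        # window is maximal iff blocked on both flanks
        left_blocked = lo == limit_lo or used == max_mismatch
        right_blocked = hi == limit_hi or used == max_mismatch
        if left_blocked and right_blocked:
            mm = sum(1 for p in left_mm if p >= lo) + sum(
                1 for p in right_mm if p < hi
            )
            out.append((lo, hi, mm))
    return out


def _scan_against(
    s: str, t: str, kind: str, min_len: int, max_mismatch: int
) -> set[RepeatPair]:
    n = len(s)
    k = max(4, (min_len - max_mismatch) // (max_mismatch + 1))
    index: dict[str, list[int]] = defaultdict(list)
    for x in range(len(t) - k + 1):
        index[t[x : x + k]].append(x)
    results: set[RepeatPair] = set()
    for a in range(len(s) - k + 1):
        for x in index.get(s[a : a + k], ()):
            d = x - a
            if kind == "forward" and d <= 0:
                continue  # self/duplicate diagonals
            for lo, hi, mm in _maximal_windows_around_seed(
                s, t, a, x, k, max_mismatch
            ):
                length = hi - lo
                if length < min_len:
                    continue
                g1 = lo
                g2 = _second_position(kind, lo + d, length, n)
                p1, p2 = sorted((g1, g2))
                if p2 < p1 + length:
                    continue  # self-overlapping pair
                results.add(RepeatPair(kind, p1, p2, length, mm))
    return results


def find_dispersed_repeats(
    sequence: str,
    min_len: int = 30,
    max_mismatch: int = 3,
    kinds: tuple[str, ...] = ("forward", "palindromic"),
) -> list[RepeatPair]:
    """Maximal repeat pairs found by exact k-mer seeding and ungapped
    extension under a Hamming-mismatch budget.

    The seed length (min_len - max_mismatch) // (max_mismatch + 1)
    guarantees by pigeonhole that every qualifying pair contains an
    exact seed, so the scan is complete.  Self-overlapping pairs are
    excluded and output is deduplicated to maximal pairs.
    """
    s = sequence.upper()
    if len(s) < 2 * min_len:
        raise ValueError("sequence shorter than twice the minimum repeat size")
    transforms = {
        "forward": s,
        "palindromic": revcomp(s),
        "reverse": s[::-1],
        "complement": s.translate(_COMP_ONLY),
    }
    results: set[RepeatPair] = set()
    for kind in kinds:
        if kind not in transforms:
            raise ValueError(f"unknown repeat kind {kind!r}")
        results |= _scan_against(s, transforms[kind], kind, min_len, max_mismatch)
    return sorted(results, key=lambda r: (r.pos1, r.pos2, -r.length, r.kind))
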