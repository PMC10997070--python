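"""Nucleotide diversity (pi), sliding-window profiles and percent-identity
profiles across aligned plastomes.

The deletion policy follows the DnaSP sliding-window convention:
columns holding a gap or N in *any* row are excluded (complete
deletion).  A pairwise-deletion variant is available behind a flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._seq import encode_states
from .records import RegionAlignment

logger = logging.getLogger(__name__)


def _encoded(alignment: RegionAlignment) -> np.ndarray:
    return np.stack(
        [encode_states("".join(row)) for row in alignment.matrix]
    )


def nucleotide_diversity(
    alignment: RegionAlignment, deletion: str = "complete"
) -> float:
    """Average pairwise proportion of nucleotide differences per site.

    pi = 2 / (n (n-1)) * sum_{i<j} d_ij with d_ij the per-site
    difference fraction over the columns retained by the deletion
    policy.  Raises if no column survives.
    """
    states = _encoded(alignment)
    n = states.shape[0]
    if n < 2:
        raise ValueError("nucleotide diversity needs >= 2 taxa")
    if deletion == "complete":
        keep = (states < 4).all(axis=0)
        if not keep.any():
            raise ValueError("no columns retained under complete deletion")
        kept = states[:, keep]
        total = 0.0
        n_pairs = 0
        m = kept.shape[1]
        for i in range(n):
            diffs = (kept[i] != kept[i + 1 :]).sum(axis=1)
            total += (diffs / m).sum()
            n_pairs += diffs.shape[0]
        return total / n_pairs
    if deletion == "pairwise":
        valid = states < 4
        total = 0.0
        n_pairs = 0
        for i in range(n):
            for j in range(i + 1, n):
                both = valid[i] & valid[j]
                m = both.sum()
                if m == 0:
                    raise ValueError(
                        f"no comparable columns between rows {i} and {j}"
                    )
                total += (states[i][both] != states[j][both]).sum() / m
                n_pairs += 1
        return total / n_pairs
    raise ValueError(f"unknown deletion policy {deletion!r}")


@dataclass
class DiversityProfile:
    windows: pd.DataFrame  # columns: start, end, pi, n_sites_used
    window_size: int
    step: int

    def max_window(self) -> pd.Series:
        return self.windows.loc[self.windows["pi"].idxmax()]


def sliding_window_pi(
    alignment: RegionAlignment,
    window: int = 600,
    step: int = 200,
    deletion: str = "complete",
) -> DiversityProfile:
    """Windowed pi at alignment-column offsets 0, step, 2*step, ...

    Only fully contained windows are evaluated; an alignment shorter
    than one window degrades to a single whole-alignment window with a
    warning.  Windows losing every column to the deletion policy get
    pi = NaN.
    """
    ncols = alignment.n_columns
    if ncols < window:
        logger.warning(
            "alignment %s shorter (%d) than window (%d); using one window",
            alignment.region_name,
            ncols,
            window,
        )
        starts = [0]
        window = ncols
    else:
        starts = list(range(0, ncols - window + 1, step))
    states = _encoded(alignment)
    keep_all = (states < 4).all(axis=0)
    rows = []
    for start in starts:
        end = start + window
        sub = alignment.subset_columns(start, end)
        n_used = int(keep_all[start:end].sum())
        try:
            pi = nucleotide_diversity(sub, deletion=deletion)
        except ValueError:
            pi = float("nan")
        rows.append(
            {"start": start, "end": end, "pi": pi, "n_sites_used": n_used}
        )
    return DiversityProfile(pd.DataFrame(rows), window, step)


def percent_identity_profile(
    alignment: RegionAlignment,
    reference_taxon: str,
    window: int = 100,
) -> pd.DataFrame:
    """mVISTA-style identity fractions versus a reference row.

    Windows are laid out in ungapped *reference* coordinates; within a
    window the identity of a row is the fraction of reference positions
    whose aligned character matches (a gap in the row counts as a
    mismatch).  Trailing partial windows are reported with their actual
    size.
    """
    if reference_taxon not in alignment.taxa:
        raise ValueError(f"unknown reference taxon {reference_taxon!r}")
    ref_row = alignment.matrix[alignment.taxa.index(reference_taxon)]
    ref_ungapped_cols = np.flatnonzero(ref_row != "-")
    n_ref = ref_ungapped_cols.size
    rows = []
    for start in range(0, n_ref, window):
        cols = ref_ungapped_cols[start : start + window]
        for taxon in alignment.taxa:
            if taxon == reference_taxon:
                continue
            other = alignment.matrix[alignment.taxa.index(taxon)][cols]
            matches = (other == ref_row[cols]).sum()
            rows.append(
                {
                    "taxon": taxon,
                    "ref_start": start,
                    "ref_end": start + cols.size,
                    "identity": matches / cols.size,
                }
            )
    return pd.DataFrame(rows)


def region_diversity_table(
    alignments: list[RegionAlignment], deletion: str = "complete"
) -> pd.DataFrame:
    """Per-region pi, sorted descending (ties broken by region name)."""
    if not alignments:
        raise ValueError("no regions given")
    rows = []
    for aln in alignments:
        try:
            pi = nucleotide_diversity(aln, deletion=deletion)
        except ValueError:
            pi = float("nan")
        rows.append(
            {
                "region": aln.region_name,
                "kind": aln.region_kind,
                "length": aln.n_columns,
                "pi": pi,
            }
        )
    table = pd.DataFrame(rows).sort_values(
        ["pi", "region"], ascending=[False, True]
    )
    return table.reset_index(drop=True)


def top_igs_regions(table: pd.DataFrame, n_igs: int = 5) -> list[str]:
    """Highest-pi intergenic spacers (the marker-candidate IGS picks)."""
    igs = table[table["kind"] == "IGS"]
    if len(igs) < n_igs:
        logger.warning("only %d IGS regions available (%d requested)", len(igs), n_igs)
    return igs["region"].head(n_igs).tolist()
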