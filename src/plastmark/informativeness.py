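"""Per-site substitution-rate estimation on a fixed ultrametric tree and
Townsend-style phylogenetic informativeness (PI) profiling.

Site rates are empirical-Bayes posterior means under the fitted
discrete-gamma model: for column i, lambda_i = sum_k r_k P(k | column),
rescaled to mean one across columns.  The per-site informativeness at
epoch T uses the four-state form rho(lambda, T) = 16 lambda e^(-4
lambda T); the constant affects absolute scale only, so rankings are
what the profile is for.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import SubstitutionModel
from .phylo import TreeLikelihood
from .records import RegionAlignment
from .trees import PhyloTree

logger = logging.getLogger(__name__)


@dataclass
class SiteRates:
    rates: np.ndarray  # per-column scaled rates, mean ~ 1
    region_map: dict[str, tuple[int, int]]  # region -> [start, end) columns
    model: SubstitutionModel

    def region_rates(self) -> dict[str, float]:
        return {
            name: float(self.rates[start:end].mean())
            for name, (start, end) in self.region_map.items()
        }


@dataclass
class PIProfile:
    epochs: np.ndarray
    net: pd.DataFrame  # rows: epochs, columns: regions
    per_site: pd.DataFrame
    region_kinds: dict[str, str]

    def ranking(self, epoch: float | None = None, per_site: bool = False) -> pd.Series:
        table = self.per_site if per_site else self.net
        if epoch is None:
            idx = len(self.epochs) - 1
        else:
            idx = int(np.argmin(np.abs(self.epochs - epoch)))
        return table.iloc[idx].sort_values(ascending=False)

    def integrated_ranking(self, per_site: bool = False) -> pd.Series:
        """Regions ranked by PI integrated over the epoch grid
        (trapezoid rule), an alternative to a single ranking epoch."""
        table = self.per_site if per_site else self.net
        areas = np.trapezoid(table.values, x=self.epochs, axis=0)
        return pd.Series(areas, index=table.columns).sort_values(
            ascending=False
        )


def townsend_informativeness(rates, epoch: float) -> np.ndarray:
    """rho(lambda, T) = 16 lambda exp(-4 lambda T), elementwise."""
    lam = np.asarray(rates, dtype=float)
    return 16.0 * lam * np.exp(-4.0 * lam * epoch)


def estimate_site_rates(
    alignment: RegionAlignment,
    tree: PhyloTree,
    model: SubstitutionModel,
    region_map: dict[str, tuple[int, int]] | None = None,
) -> SiteRates:
    """Posterior-mean site rates on the fixed (ultrametric) tree.

    Constant columns end up below the mean, saturated columns above;
    with a single rate category every column gets rate one.
    """
    engine = TreeLikelihood(tree, alignment, model)
    cat_rates = model.category_rates()
    if len(cat_rates) == 1:
        rates = np.ones(alignment.n_columns)
    else:
        from ._seq import encode_states

        posteriors = engine.column_category_posteriors()  # (ncols_kept, ncat)
        kept_rates = posteriors @ cat_rates
        # all-missing columns were dropped by the engine; give them the mean
        stacked = np.stack(
            [encode_states(alignment.row(t)) for t in alignment.taxa]
        )
        keep = (stacked < 4).any(axis=0)
        rates = np.full(alignment.n_columns, float(kept_rates.mean()))
        rates[keep] = kept_rates
        if not keep.all():
            logger.info(
                "%d all-missing columns received the mean rate",
                int((~keep).sum()),
            )
    rates = rates / rates.mean()
    return SiteRates(
        rates=rates,
        region_map=region_map or {alignment.region_name: (0, alignment.n_columns)},
        model=model,
    )


def pi_profile(
    site_rates: SiteRates,
    epochs,
    region_kinds: dict[str, str] | None = None,
) -> PIProfile:
    """Net and per-site PI per region over a grid of epochs."""
    epochs = np.asarray(epochs, dtype=float)
    if (epochs <= 0).any():
        raise ValueError("epochs must be positive")
    net = {}
    per_site = {}
    for region, (start, end) in site_rates.region_map.items():
        lam = site_rates.rates[start:end]
        rho = np.array(
            [townsend_informativeness(lam, t).sum() for t in epochs]
        )
        net[region] = rho
        per_site[region] = rho / max(end - start, 1)
    return PIProfile(
        epochs=epochs,
        net=pd.DataFrame(net, index=epochs),
        per_site=pd.DataFrame(per_site, index=epochs),
        region_kinds=region_kinds or {},
    )


@dataclass
class CandidateSet:
    genes: list[str]
    igs: list[str]
    gene_ranks: pd.Series
    igs_ranks: pd.Series

    @property
    def regions(self) -> list[str]:
        return self.genes + self.igs


def rank_candidate_regions(
    profile: PIProfile,
    diversity_table: pd.DataFrame,
    epoch: float | None = None,
    n_genes: int = 5,
    n_igs: int = 5,
    per_site: bool = False,
) -> CandidateSet:
    """Top genes by net PI at the ranking epoch; top IGS by pi.

    The default ranking epoch is the deepest epoch of the profile grid
    (the crown age when the grid ends there).
    """
    ranking = profile.ranking(epoch=epoch, per_site=per_site)
    kinds = profile.region_kinds
    gene_ranking = ranking[[r for r in ranking.index if kinds.get(r) == "gene"]]
    if len(gene_ranking) < n_genes:
        logger.warning(
            "only %d gene regions available (%d requested)",
            len(gene_ranking),
            n_genes,
        )
    igs_table = diversity_table[diversity_table["kind"] == "IGS"]
    igs_ranking = igs_table.set_index("region")["pi"]
    if len(igs_ranking) < n_igs:
        logger.warning(
            "only %d IGS regions available (%d requested)", len(igs_ranking), n_igs
        )
    return CandidateSet(
        genes=list(gene_ranking.head(n_genes).index),
        igs=list(igs_ranking.head(n_igs).index),
        gene_ranks=gene_ranking,
        igs_ranks=igs_ranking,
    )
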