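"""Synthetic plastome-like datasets with known truth.

The generator evolves named gene/IGS regions along a known ultrametric
tree under a reversible substitution model with region-specific rate
multipliers, assembles circular quadripartite genomes (LSC + IRb + SSC
+ IRa, the IRa being the exact reverse complement of IRb), plants
microsatellites at recorded coordinates, and emits truth tables so
every downstream stage can be scored against the planted signal.

The default preset emulates a genus-level plastome panel: 20 taxa,
low overall divergence (mean pairwise ~0.02 substitutions/site),
AT-rich base composition, IR regions evolving several-fold slower than
single-copy regions and intergenic spacers faster than genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from ._seq import NUC_ORDER, revcomp
from .models import SubstitutionModel
from .records import Feature, PlastomeRecord, RegionAlignment
from .structure import QuadripartitePartition
from .trees import Node, PhyloTree


@dataclass
class RegionSpec:
    name: str
    kind: str  # "gene" or "IGS"
    length: int
    rate_multiplier: float
    segment: str = "LSC"  # LSC | SSC | IR

    def __post_init__(self) -> None:
        if self.kind not in ("gene", "IGS"):
            raise ValueError(f"region kind must be gene/IGS, got {self.kind!r}")
        if self.segment not in ("LSC", "SSC", "IR"):
            raise ValueError(f"segment must be LSC/SSC/IR, got {self.segment!r}")
        if self.length < 1 or self.rate_multiplier < 0:
            raise ValueError(f"invalid region spec {self.name!r}")


@dataclass
class SSRPlant:
    motif: str
    n_repeats: int
    region: str


@dataclass
class SimulationConfig:
    n_taxa: int = 20
    birth_rate: float = 1.0
    regions: list[RegionSpec] = field(default_factory=list)
    model: SubstitutionModel = field(
        default_factory=lambda: SubstitutionModel.gtr(
            freqs=[0.31, 0.19, 0.19, 0.31],
            exchangeabilities=[1.2, 3.0, 0.8, 1.1, 3.2, 1.0],
            alpha=1.0,
            ncat=4,
        )
    )
    mean_pairwise_divergence: float = 0.02
    tree_newick: str | None = None
    ssr_plants: list[SSRPlant] = field(default_factory=list)
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "n_taxa": self.n_taxa,
            "birth_rate": self.birth_rate,
            "mean_pairwise_divergence": self.mean_pairwise_divergence,
            "tree_newick": self.tree_newick,
            "seed": self.seed,
            "model": {
                "kind": self.model.kind,
                "freqs": [float(f) for f in self.model.freqs],
                "exchangeabilities": [
                    float(r) for r in self.model.exchangeabilities
                ],
                "alpha": self.model.alpha,
                "ncat": self.model.ncat,
            },
            "regions": [
                {
                    "name": r.name,
                    "kind": r.kind,
                    "length": r.length,
                    "rate_multiplier": r.rate_multiplier,
                    "segment": r.segment,
                }
                for r in self.regions
            ],
            "ssr_plants": [
                {"motif": p.motif, "n_repeats": p.n_repeats, "region": p.region}
                for p in self.ssr_plants
            ],
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        data = yaml.safe_load(Path(path).read_text())
        model_data = data.get("model", {})
        model = SubstitutionModel(
            kind=model_data.get("kind", "GTR"),
            freqs=np.asarray(model_data.get("freqs", [0.25] * 4)),
            exchangeabilities=np.asarray(
                model_data.get("exchangeabilities", [1.0] * 6)
            ),
            alpha=model_data.get("alpha"),
            ncat=model_data.get("ncat", 4),
        )
        return cls(
            n_taxa=data.get("n_taxa", 20),
            birth_rate=data.get("birth_rate", 1.0),
            regions=[RegionSpec(**r) for r in data.get("regions", [])],
            model=model,
            mean_pairwise_divergence=data.get("mean_pairwise_divergence", 0.02),
            tree_newick=data.get("tree_newick"),
            ssr_plants=[SSRPlant(**p) for p in data.get("ssr_plants", [])],
            seed=data.get("seed", 0),
        )


@dataclass
class SyntheticTruth:
    true_tree: PhyloTree
    true_region_rates: dict[str, float]
    true_partition: QuadripartitePartition | None
    region_coords: dict[str, tuple[int, int]]
    true_ssr_coords: list[dict]


@dataclass
class SyntheticDataset:
    records: list[PlastomeRecord]
    truth: SyntheticTruth
    region_alignments: dict[str, RegionAlignment]

    def genome_alignment(self) -> RegionAlignment:
        """Whole-genome alignment (gap-free by construction)."""
        return RegionAlignment.from_sequences(
            "whole_genome",
            "genome",
            [(r.accession, r.sequence) for r in self.records],
        )


# ------------------------------------------------------------------ tree sim


def simulate_tree(
    n_taxa: int,
    birth_rate: float = 1.0,
    seed: int | None = 0,
    rng: np.random.Generator | None = None,
) -> PhyloTree:
    """Ultrametric Yule (pure-birth) tree with equal tip depths.

    Lineages split at exponential waiting times; after the n-th
    lineage appears a final exponential wait sets the present.
    """
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    if birth_rate <= 0:
        raise ValueError("birth rate must be positive")
    rng = rng if rng is not None else np.random.default_rng(seed)
    root = Node(None, 0.0, [Node(), Node()])
    active: list[tuple[Node, float]] = [(root.children[0], 0.0), (root.children[1], 0.0)]
    t = 0.0
    while len(active) < n_taxa:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        idx = int(rng.integers(len(active)))
        node, born = active.pop(idx)
        node.length = t - born
        node.children = [Node(), Node()]
        active.append((node.children[0], t))
        active.append((node.children[1], t))
    t += rng.exponential(1.0 / (birth_rate * n_taxa))
    width = len(str(n_taxa))
    tip_set = {id(node) for node, _ in active}
    born_of = {id(node): born for node, born in active}
    counter = 0
    stack = [root]
    # deterministic naming in traversal order
    while stack:
        node = stack.pop()
        if id(node) in tip_set:
            counter += 1
            node.name = f"t{counter:0{width}d}"
            node.length = t - born_of[id(node)]
        stack.extend(reversed(node.children))
    return PhyloTree(root)


# -------------------------------------------------------------- sequence sim


def simulate_region_alignment(
    tree: PhyloTree,
    length: int,
    multiplier: float,
    model: SubstitutionModel,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    region_name: str = "region",
    region_kind: str = "gene",
) -> RegionAlignment:
    """Evolve one gap-free region along the tree.

    Sites are i.i.d. given a discrete-gamma site rate (when the model
    carries alpha); the region multiplier scales every branch length.
    """
    if length < 1:
        raise ValueError("region length must be >= 1")
    if multiplier < 0:
        raise ValueError("rate multiplier must be >= 0")
    rng = rng if rng is not None else np.random.default_rng(seed)
    cat_rates = model.category_rates()
    site_cat = (
        rng.integers(len(cat_rates), size=length)
        if len(cat_rates) > 1
        else np.zeros(length, dtype=int)
    )
    root_states = rng.choice(4, size=length, p=model.freqs)
    states: dict[int, np.ndarray] = {id(tree.root): root_states}
    for node in tree.preorder():
        for child in node.children:
            parent_states = states[id(node)]
            child_states = parent_states.copy()
            t = child.length * multiplier
            if t > 0:
                for cat in range(len(cat_rates)):
                    mask = site_cat == cat
                    if not mask.any():
                        continue
                    pmat = model.transition_matrix(t * cat_rates[cat])
                    cum = np.cumsum(pmat, axis=1)
                    cum[:, -1] = 1.0
                    u = rng.random(int(mask.sum()))
                    child_states[mask] = (
                        u[:, None] > cum[parent_states[mask]]
                    ).sum(axis=1)
            states[id(child)] = child_states
    lookup = np.array(list(NUC_ORDER), dtype="U1")
    named = [
        (name, "".join(lookup[states[id(tip)]]))
        for name, tip in zip(tree.tip_names(), tree.tips())
    ]
    return RegionAlignment.from_sequences(region_name, region_kind, named)


# ------------------------------------------------------------------ assembly


def _pick_base_not(*forbidden: str) -> str:
    for base in NUC_ORDER:
        if base not in forbidden:
            return base
    raise AssertionError("unreachable")


def assemble_synthetic_plastomes(
    config: SimulationConfig,
) -> SyntheticDataset:
    """Simulate regions, lay out quadripartite genomes, plant SSRs.

    Genome = LSC regions + IRb regions + SSC regions + revcomp(IRb
    block).  The bases flanking the IR junctions are adjusted so the
    planted IR pair is exactly maximal, and planted SSR tracts are made
    maximal the same way.  Returns records, truth tables, and the
    per-region alignments.
    """
    if not config.regions:
        raise ValueError("no regions configured")
    rng = np.random.default_rng(config.seed)
    if config.tree_newick:
        tree = PhyloTree.from_newick(config.tree_newick)
    else:
        tree = simulate_tree(config.n_taxa, config.birth_rate, rng=rng)
    if config.mean_pairwise_divergence > 0:
        tree = tree.scale(
            config.mean_pairwise_divergence / tree.mean_pairwise_distance()
        )
    taxa = tree.tip_names()

    alignments: dict[str, RegionAlignment] = {}
    for spec in config.regions:
        alignments[spec.name] = simulate_region_alignment(
            tree,
            spec.length,
            spec.rate_multiplier,
            config.model,
            rng=rng,
            region_name=spec.name,
            region_kind=spec.kind,
        )

    # plant SSRs (same coordinates in every taxon, centred in the host)
    by_name = {spec.name: spec for spec in config.regions}
    ssr_truth: list[dict] = []
    for plant in config.ssr_plants:
        if plant.region not in by_name:
            raise ValueError(f"SSR host region {plant.region!r} not configured")
        spec = by_name[plant.region]
        u = len(plant.motif)
        tract_len = u * plant.n_repeats
        if tract_len + 2 > spec.length:
            raise ValueError(
                f"SSR {plant.motif}x{plant.n_repeats} exceeds host "
                f"region {plant.region!r} ({spec.length} bp)"
            )
        start = max(1, (spec.length - tract_len) // 2)
        mat = alignments[plant.region].matrix
        tract = np.array(list(plant.motif * plant.n_repeats), dtype="U1")
        mat[:, start : start + tract_len] = tract
        # break periodic extension on both flanks
        mat[:, start - 1] = _pick_base_not(plant.motif[-1])
        if start + tract_len < spec.length:
            mat[:, start + tract_len] = _pick_base_not(plant.motif[0])
        ssr_truth.append(
            {
                "region": plant.region,
                "motif": plant.motif,
                "n_repeats": plant.n_repeats,
                "region_start": start,
                "region_end": start + tract_len,
            }
        )

    # genome layout: LSC | IRb | SSC | IRa
    layout = [
        spec
        for segment in ("LSC", "IR", "SSC")
        for spec in config.regions
        if spec.segment == segment
    ]
    region_coords: dict[str, tuple[int, int]] = {}
    offset = 0
    for spec in layout:
        region_coords[spec.name] = (offset, offset + spec.length)
        offset += spec.length
    lsc_len = sum(s.length for s in config.regions if s.segment == "LSC")
    ir_len = sum(s.length for s in config.regions if s.segment == "IR")
    ssc_len = sum(s.length for s in config.regions if s.segment == "SSC")
    if ir_len == 0 or lsc_len <= ssc_len:
        raise ValueError(
            "template needs a nonempty IR and LSC longer than SSC"
        )
    l1, l2, l3 = lsc_len, lsc_len + ir_len, lsc_len + ir_len + ssc_len
    n = l3 + ir_len

    # genome-coordinate SSR truth (first-copy coordinates)
    for entry in ssr_truth:
        r0, _ = region_coords[entry["region"]]
        entry["start"] = r0 + entry["region_start"]
        entry["end"] = r0 + entry["region_end"]

    records: list[PlastomeRecord] = []
    row_cache = {
        spec.name: {
            taxon: alignments[spec.name].row(taxon) for taxon in taxa
        }
        for spec in config.regions
    }
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    features_template: list[Feature] = []
    for spec in layout:
        if spec.kind != "gene":
            continue
        start, end = region_coords[spec.name]
        features_template.append(
            Feature(spec.name, "gene", "+", [(start, end)])
        )
        if spec.segment == "IR":
            # mirrored copy inside IRa
            rel_s, rel_e = start - l1, end - l1
            ira_s = l3 + (ir_len - rel_e)
            ira_e = l3 + (ir_len - rel_s)
            features_template.append(
                Feature(spec.name, "gene", "-", [(ira_s, ira_e)])
            )

    for taxon in taxa:
        parts = [row_cache[spec.name][taxon] for spec in layout]
        core = "".join(parts)
        genome = core + revcomp(core[l1:l2])
        glist = list(genome)
        # sharpen IR boundaries so the IR pair is exactly maximal:
        # right extension pairs first SSC base with last SSC base,
        # left extension pairs last LSC base with first LSC base.
        if glist[l2] == comp[glist[l3 - 1]]:
            glist[l2] = _pick_base_not(comp[glist[l3 - 1]])
        if glist[l1 - 1] == comp[glist[0]]:
            glist[l1 - 1] = _pick_base_not(comp[glist[0]])
        genome = "".join(glist)
        # propagate the sharpening edits back into the region alignments
        first_ssc = next(s for s in layout if s.segment == "SSC")
        last_lsc = [s for s in layout if s.segment == "LSC"][-1]
        row_idx = alignments[first_ssc.name].taxa.index(taxon)
        alignments[first_ssc.name].matrix[row_idx, 0] = genome[l2]
        row_idx = alignments[last_lsc.name].taxa.index(taxon)
        alignments[last_lsc.name].matrix[row_idx, -1] = genome[l1 - 1]
        records.append(
            PlastomeRecord(
                accession=taxon,
                sequence=genome,
                circular=True,
                features=[
                    Feature(f.name, f.kind, f.strand, list(f.intervals))
                    for f in features_template
                ],
            )
        )

    truth = SyntheticTruth(
        true_tree=tree,
        true_region_rates={s.name: s.rate_multiplier for s in config.regions},
        true_partition=QuadripartitePartition(
            genome_length=n,
            lsc=(0, l1),
            irb=(l1, l2),
            ssc=(l2, l3),
            ira=(l3, n),
        ),
        region_coords=region_coords,
        true_ssr_coords=ssr_truth,
    )
    return SyntheticDataset(
        records=records, truth=truth, region_alignments=alignments
    )


# ------------------------------------------------------------------- presets


def iris_like_config(seed: int = 0, n_taxa: int = 20) -> SimulationConfig:
    """Desk-scale preset mirroring a genus-level plastome panel.

    ~30 regions over a ~35 kb genome (instead of ~150 kb), quadripartite
    layout, IR regions several-fold slower than single-copy regions,
    spacers faster than genes, a few hypervariable regions, and planted
    SSRs spanning unit sizes 1-6.
    """
    regions: list[RegionSpec] = []

    def add_block(prefix, segment, gene_lens, igs_len, gene_mult, igs_mult,
                  hyper: dict[int, float] | None = None):
        hyper = hyper or {}
        for i, glen in enumerate(gene_lens, start=1):
            regions.append(
                RegionSpec(
                    f"{prefix}{i:02d}",
                    "gene",
                    glen,
                    hyper.get(i, gene_mult),
                    segment,
                )
            )
            if i < len(gene_lens):
                regions.append(
                    RegionSpec(
                        f"{prefix}{i:02d}-{prefix}{i+1:02d}",
                        "IGS",
                        igs_len,
                        hyper.get(-i, igs_mult),
                        segment,
                    )
                )

    # LSC: 9 genes + 8 spacers; one hypervariable gene and spacer
    add_block(
        "g", "LSC",
        [1200, 900, 1800, 600, 1050, 900, 1500, 750, 1200],
        420, 0.8, 1.6,
        hyper={3: 2.5, -4: 2.6},
    )
    # IR: 3 genes + 2 spacers, slow
    add_block("r", "IR", [1200, 1800, 900], 330, 0.35, 0.35)
    # SSC: 4 genes + 3 spacers, fast
    add_block("s", "SSC", [900, 1500, 600, 900], 380, 1.3, 2.2, hyper={2: 2.0})

    ssr_plants = [
        SSRPlant("A", 12, "g01-g02"),
        SSRPlant("T", 10, "g05-g06"),
        SSRPlant("AT", 7, "g02-g03"),
        SSRPlant("AAT", 5, "s01-s02"),
        SSRPlant("AATC", 4, "g06-g07"),
        SSRPlant("AATAC", 3, "s02-s03"),
        SSRPlant("AATGCC", 3, "g08-g09"),
    ]
    return SimulationConfig(
        n_taxa=n_taxa, regions=regions, ssr_plants=ssr_plants, seed=seed
    )


def marker_screen_config(seed: int = 0, n_taxa: int = 20) -> SimulationConfig:
    """Preset for the marker-combination screen.

    Eight single-copy 1 kb gene regions, three carrying strong signal
    (2.5x rate) and five nearly uninformative (0.15x), evolved on one
    fixed representative 20-taxon phylogeny whose internode lengths mix
    easy and hard splits.  Calibrated so the screen operates in the
    graded regime of real plastome studies: no single region resolves
    the reference perfectly, while the high-signal concatenations come
    close.  Within-region rates are homogeneous; rate variation enters
    only through the region multipliers, so fast-mode JC distances stay
    consistent.  The seed varies sequence evolution on the fixed tree.
    """
    regions = [
        RegionSpec(f"m{i:02d}", "gene", 1000, 2.5 if i <= 3 else 0.15, "LSC")
        for i in range(1, 9)
    ]
    # minimal IR/SSC so the genome remains assemblable if needed
    regions.append(RegionSpec("ir01", "gene", 1200, 0.2, "IR"))
    regions.append(RegionSpec("ss01", "gene", 900, 0.5, "SSC"))
    model = SubstitutionModel.gtr(
        freqs=[0.31, 0.19, 0.19, 0.31],
        exchangeabilities=[1.2, 3.0, 0.8, 1.1, 3.2, 1.0],
        alpha=None,
        ncat=1,
    )
    fixed_tree = simulate_tree(n_taxa, birth_rate=1.0, seed=11).to_newick()
    return SimulationConfig(
        n_taxa=n_taxa,
        regions=regions,
        seed=seed,
        model=model,
        tree_newick=fixed_tree,
    )
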