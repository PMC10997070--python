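"""End-to-end orchestration: simulate (or load), structure, diversity,
codon usage, whole-concatenation tree, ultrametricization, per-site
rates/PI, candidate selection, and the combination screen.

Each stage writes its artifacts under the output directory and records
a config fingerprint, so re-runs with an unchanged config reload
cached intermediates instead of recomputing.  One global seed
deterministically derives per-stage seeds by stage-name hashing.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .codon_usage import codon_usage, start_codon_summary
from .diversity import (
    nucleotide_diversity,
    region_diversity_table,
    sliding_window_pi,
)
from .informativeness import (
    estimate_site_rates,
    pi_profile,
    rank_candidate_regions,
)
from .markers import ScreenConfig, ranking_table, screen_combinations
from .models import SubstitutionModel
from .phylo import (
    MLSearchConfig,
    TreeLikelihood,
    _fit_model_params,
    bootstrap_support,
    fast_jc_distance_matrix,
    make_ultrametric,
    neighbor_joining,
    optimize_ml_tree,
    pairwise_differences,
)
from .records import RegionAlignment, concatenate_alignments
from .simulate import (
    SimulationConfig,
    SyntheticDataset,
    assemble_synthetic_plastomes,
    iris_like_config,
)
from .structure import (
    find_quadripartite,
    junction_report,
    scan_ssrs,
    ssr_summary,
)
from .io import gc_content

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


class PipelineConfigError(ValueError):
    pass


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, original: Exception) -> None:
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


@dataclass
class PipelineConfig:
    mode: str = "synthetic"  # synthetic | real
    out_dir: str = "plastmark_out"
    seed: int = 1
    # synthetic inputs
    simulation: SimulationConfig = field(default_factory=iris_like_config)
    # real inputs
    genbank_dir: str | None = None
    alignment_dir: str | None = None
    # analysis parameters
    window: int = 600
    step: int = 200
    min_ir_len: int = 1000
    n_genes: int = 5
    n_igs: int = 5
    metric: str = "cis"
    bootstrap: int = 0
    tree_mode: str = "fast"  # fast (NJ + fitted branch lengths) | ml (NNI search)
    plots: bool = False
    strict: bool = False

    def validate(self) -> None:
        if self.mode not in ("synthetic", "real"):
            raise PipelineConfigError(f"unknown mode {self.mode!r}")
        if self.mode == "real":
            for attr in ("genbank_dir", "alignment_dir"):
                value = getattr(self, attr)
                if value is None or not Path(value).is_dir():
                    raise PipelineConfigError(
                        f"real mode requires existing {attr} (got {value!r})"
                    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        sim_data = data.pop("simulation", None)
        config = cls(**{k: v for k, v in data.items() if k != "simulation"})
        if sim_data is not None:
            import tempfile

            with tempfile.NamedTemporaryFile("w", suffix=".yaml", delete=False) as fh:
                yaml.safe_dump(sim_data, fh)
                tmp = fh.name
            config.simulation = SimulationConfig.from_yaml(tmp)
            Path(tmp).unlink()
        return config

    def fingerprint(self) -> str:
        def default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            return str(o)

        payload = json.dumps(
            dataclasses.asdict(self), default=default, sort_keys=True
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def stage_seed(global_seed: int, stage: str) -> int:
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunReport:
    config_fingerprint: str
    version: str
    seed: int
    stages: dict = field(default_factory=dict)
    timings: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "version": self.version,
                "config_fingerprint": self.config_fingerprint,
                "seed": self.seed,
                "stages": self.stages,
                "timings": {k: round(v, 3) for k, v in self.timings.items()},
            },
            indent=2,
            sort_keys=True,
        )


class Pipeline:
    def __init__(self, config: PipelineConfig) -> None:
        config.validate()
        self.config = config
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.report = RunReport(
            config_fingerprint=config.fingerprint(),
            version=__version__,
            seed=config.seed,
        )
        self._manifest_path = self.out / "manifest.json"
        self._manifest = (
            json.loads(self._manifest_path.read_text())
            if self._manifest_path.exists()
            else {}
        )

    # ------------------------------------------------------------- caching

    def _cached(self, stage: str, path: Path) -> bool:
        return (
            self._manifest.get(stage) == self.report.config_fingerprint
            and path.exists()
        )

    def _mark(self, stage: str) -> None:
        self._manifest[stage] = self.report.config_fingerprint
        self._manifest_path.write_text(json.dumps(self._manifest, indent=2))

    # -------------------------------------------------------------- stages

    def run(self) -> RunReport:
        stages = [
            ("data", self._stage_data),
            ("structure", self._stage_structure),
            ("diversity", self._stage_diversity),
            ("codons", self._stage_codons),
            ("tree", self._stage_tree),
            ("informativeness", self._stage_informativeness),
            ("screen", self._stage_screen),
        ]
        for name, fn in stages:
            t0 = time.perf_counter()
            try:
                fn()
            except PipelineStageError:
                raise
            except Exception as exc:  # noqa: BLE001 - rewrap with stage name
                raise PipelineStageError(name, exc) from exc
            self.report.timings[name] = time.perf_counter() - t0
            self._mark(name)
        (self.out / "report.json").write_text(self.report.to_json())
        return self.report

    def _stage_data(self) -> None:
        if self.config.mode == "synthetic":
            sim = dataclasses.replace(
                self.config.simulation,
                seed=stage_seed(self.config.seed, "simulate"),
            )
            dataset = assemble_synthetic_plastomes(sim)
            self.dataset: SyntheticDataset | None = dataset
            self.records = dataset.records
            self.alignments = dataset.region_alignments
            self.genome_aln = dataset.genome_alignment()
            truth_dir = self.out / "truth"
            truth_dir.mkdir(exist_ok=True)
            pio.write_newick(dataset.truth.true_tree, truth_dir / "true_tree.nwk")
            pd.DataFrame(
                [
                    {"region": k, "rate_multiplier": v}
                    for k, v in dataset.truth.true_region_rates.items()
                ]
            ).to_csv(truth_dir / "region_rates.tsv", sep="\t", index=False)
        else:
            self.dataset = None
            gb_dir = Path(self.config.genbank_dir)
            self.records = [
                pio.read_genbank(p)
                for p in sorted(gb_dir.glob("*.gb"))
                + sorted(gb_dir.glob("*.gbk"))
            ]
            if not self.records:
                raise PipelineConfigError(f"no GenBank files under {gb_dir}")
            self.alignments = {}
            aln_dir = Path(self.config.alignment_dir)
            for p in sorted(aln_dir.glob("*.fasta")) + sorted(aln_dir.glob("*.fa")):
                aln = pio.read_fasta_alignment(p)
                self.alignments[aln.region_name] = aln
            genome_path = aln_dir / "whole_genome.aln"
            self.genome_aln = (
                pio.read_fasta_alignment(genome_path, "whole_genome", "genome")
                if genome_path.exists()
                else None
            )
        self.report.stages["data"] = {
            "mode": self.config.mode,
            "n_genomes": len(self.records),
            "n_regions": len(self.alignments),
        }

    def _stage_structure(self) -> None:
        rows = []
        partitions = []
        ssr_rows = []
        for record in self.records:
            try:
                part = find_quadripartite(record, self.config.min_ir_len)
                partitions.append((record, part))
                lengths = part.lengths()
            except ValueError as exc:
                if self.config.strict:
                    raise
                logger.warning("%s: %s", record.accession, exc)
                lengths = {}
            ssrs = scan_ssrs(record.sequence)
            summary = ssr_summary(ssrs)
            ssr_rows.append(
                {
                    "accession": record.accession,
                    **{f"unit_{u}": c for u, c in summary["by_unit"].items()},
                    "total": summary["total"],
                    "compound": summary["compound"],
                }
            )
            rows.append(
                {
                    "accession": record.accession,
                    "total_length": len(record),
                    "gc_content": round(gc_content(record.sequence), 4),
                    "n_genes": len(record.genes()),
                    **{k: v for k, v in lengths.items()},
                }
            )
        genome_table = pd.DataFrame(rows)
        ssr_table = pd.DataFrame(ssr_rows)
        junctions = junction_report(partitions) if partitions else pd.DataFrame()
        genome_table.to_csv(self.out / "genomes.tsv", sep="\t", index=False)
        ssr_table.to_csv(self.out / "ssr_counts.tsv", sep="\t", index=False)
        junctions.to_csv(self.out / "junctions.tsv", sep="\t", index=False)
        self.partitions = partitions
        self.report.stages["structure"] = {
            "genomes": genome_table.to_dict(orient="records"),
            "ssr_totals": {
                row["accession"]: row["total"] for row in ssr_rows
            },
        }

    def _stage_diversity(self) -> None:
        table = region_diversity_table(list(self.alignments.values()))
        table.to_csv(self.out / "region_diversity.tsv", sep="\t", index=False)
        summary: dict = {
            "regions": table.to_dict(orient="records"),
        }
        if self.genome_aln is not None:
            profile = sliding_window_pi(
                self.genome_aln, self.config.window, self.config.step
            )
            profile.windows.to_csv(
                self.out / "pi_windows.tsv", sep="\t", index=False
            )
            summary["mean_window_pi"] = float(profile.windows["pi"].mean())
            if self.partitions:
                part = self.partitions[0][1]
                mids = (profile.windows["start"] + profile.windows["end"]) / 2
                seg_means = {}
                for seg_name in ("LSC", "SSC", "IRa", "IRb"):
                    interval = getattr(part, seg_name.lower())
                    lo, hi = interval[0], interval[1]
                    inside = (mids >= lo) & (mids < hi)
                    if inside.any():
                        seg_means[seg_name] = float(
                            profile.windows.loc[inside, "pi"].mean()
                        )
                summary["segment_mean_pi"] = seg_means
            if self.config.plots:
                self._plot_pi(profile)
        self.diversity_table = table
        self.report.stages["diversity"] = summary

    def _stage_codons(self) -> None:
        record = self.records[0]
        genes: dict[str, str] = {}
        for feat in record.genes():
            genes.setdefault(feat.name, record.feature_sequence(feat))
        named = sorted(genes.items())
        table = codon_usage([seq for _, seq in named])
        initiators, histogram = start_codon_summary(named)
        table.to_frame().to_csv(self.out / "codon_usage.tsv", sep="\t", index=False)
        self.report.stages["codons"] = {
            "accession": record.accession,
            "n_genes": table.n_genes,
            "total_codons": table.total_codons,
            "rscu_ATG": table.rscu.get("ATG"),
            "rscu_TGG": table.rscu.get("TGG"),
            "start_codons": dict(histogram),
            "ending_composition": table.ending_composition(),
        }

    def _stage_tree(self) -> None:
        taxa = sorted(self.alignments[next(iter(self.alignments))].taxa)
        concat, region_map = concatenate_alignments(
            [aln.reorder(taxa) for aln in self.alignments.values()]
        )
        self.concat = concat
        self.region_map = region_map
        if len(taxa) < 4:
            logger.warning("fewer than 4 taxa; tree stages skipped")
            self.ml_tree = None
            self.report.stages["tree"] = {"skipped": "fewer than 4 taxa"}
            return
        model_path = self.out / "fitted_model.json"
        tree_path = self.out / "plastome_tree.nwk"
        ultra_path = self.out / "ultrametric_tree.nwk"
        if self._cached("tree", model_path) and tree_path.exists() and ultra_path.exists():
            cached = json.loads(model_path.read_text())
            self.ml_tree = pio.read_newick(tree_path)
            self.ultrametric = pio.read_newick(ultra_path)
            self.fitted_model = SubstitutionModel(
                kind=cached["kind"],
                freqs=np.asarray(cached["freqs"]),
                exchangeabilities=np.asarray(cached["exchangeabilities"]),
                alpha=cached["alpha"],
                ncat=cached["ncat"],
            )
            self.report.stages["tree"] = cached["report"]
            return
        if self.config.tree_mode == "ml":
            result = optimize_ml_tree(
                concat,
                MLSearchConfig(seed=stage_seed(self.config.seed, "tree")),
            )
            tree, model, lnl = result.tree, result.model, result.lnl
        else:
            diffs, shared = pairwise_differences(concat)
            dmat = fast_jc_distance_matrix(diffs, np.clip(shared, 1.0, None))
            tree = neighbor_joining(
                pd.DataFrame(dmat, index=concat.taxa, columns=concat.taxa)
            )
            model = SubstitutionModel.gtr(
                np.full(4, 0.25), np.ones(6), alpha=1.0, ncat=4
            ).with_params(freqs=_empirical(concat))
            engine = TreeLikelihood(tree, concat, model)
            engine.optimize_branch_lengths(max_passes=1)
            model = _fit_model_params(tree, concat, model)
            engine = TreeLikelihood(tree, concat, model)
            lnl = engine.optimize_branch_lengths(max_passes=1)
        if self.config.bootstrap > 0:
            tree = bootstrap_support(
                concat,
                tree,
                MLSearchConfig(
                    n_bootstrap=self.config.bootstrap,
                    seed=stage_seed(self.config.seed, "bootstrap"),
                ),
            )
        self.ml_tree = tree
        self.fitted_model = model
        self.ultrametric = make_ultrametric(tree)
        pio.write_newick(tree, tree_path, include_support=True)
        pio.write_newick(self.ultrametric, ultra_path)
        self.report.stages["tree"] = {
            "lnl": float(lnl),
            "model": model.short_name(),
            "alpha": model.alpha,
            "n_taxa": len(taxa),
            "concat_length": concat.n_columns,
        }
        model_path.write_text(
            json.dumps(
                {
                    "kind": model.kind,
                    "freqs": [float(f) for f in model.freqs],
                    "exchangeabilities": [
                        float(r) for r in model.exchangeabilities
                    ],
                    "alpha": model.alpha,
                    "ncat": model.ncat,
                    "report": self.report.stages["tree"],
                },
                indent=2,
            )
        )

    def _stage_informativeness(self) -> None:
        if self.ml_tree is None:
            self.candidates = None
            self.report.stages["informativeness"] = {"skipped": "no tree"}
            return
        rates = estimate_site_rates(
            self.concat, self.ultrametric, self.fitted_model, self.region_map
        )
        root_age = max(self.ultrametric.tip_depths().values())
        epochs = np.linspace(root_age / 16.0, root_age, 16)
        kinds = {
            aln.region_name: aln.region_kind for aln in self.alignments.values()
        }
        profile = pi_profile(rates, epochs, kinds)
        profile.net.to_csv(self.out / "pi_profile_net.tsv", sep="\t")
        profile.per_site.to_csv(self.out / "pi_profile_per_site.tsv", sep="\t")
        self.candidates = rank_candidate_regions(
            profile,
            self.diversity_table,
            n_genes=self.config.n_genes,
            n_igs=self.config.n_igs,
        )
        (self.out / "candidates.json").write_text(
            json.dumps(
                {"genes": self.candidates.genes, "igs": self.candidates.igs},
                indent=2,
            )
        )
        self.report.stages["informativeness"] = {
            "candidate_genes": self.candidates.genes,
            "candidate_igs": self.candidates.igs,
        }

    def _stage_screen(self) -> None:
        if self.ml_tree is None or self.candidates is None:
            self.report.stages["screen"] = {"skipped": "no tree"}
            return
        results = screen_combinations(
            self.alignments,
            self.candidates.regions,
            self.ml_tree,
            ScreenConfig(
                metric=self.config.metric,
                seed=stage_seed(self.config.seed, "screen"),
            ),
        )
        table = ranking_table(results)
        table.to_csv(self.out / "combination_ranking.tsv", sep="\t", index=False)
        best = results[0]
        pio.write_newick(best.tree, self.out / "best_subset_tree.nwk")
        self.report.stages["screen"] = {
            "n_subsets": len(results),
            "best_subset": list(best.subset),
            "best_score_cis": best.score_cis,
            "best_score_rf": best.score_rf_normalized,
        }

    # --------------------------------------------------------------- plots

    def _plot_pi(self, profile) -> None:  # pragma: no cover - optional artifact
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(10, 3))
        mids = (profile.windows["start"] + profile.windows["end"]) / 2
        ax.plot(mids, profile.windows["pi"], lw=1)
        if self.partitions:
            part = self.partitions[0][1]
            for pos in part.junctions.values():
                ax.axvline(pos, ls="--", color="grey", lw=0.8)
        ax.set_xlabel("alignment position (bp)")
        ax.set_ylabel("nucleotide diversity (pi)")
        fig.tight_layout()
        fig.savefig(self.out / "pi_profile.png", dpi=150)
        plt.close(fig)


def _empirical(alignment: RegionAlignment) -> np.ndarray:
    from .phylo import _empirical_freqs

    return _empirical_freqs(alignment)


def run_pipeline(config: PipelineConfig) -> RunReport:
    return Pipeline(config).run()
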