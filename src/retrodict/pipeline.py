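"""End-to-end orchestration: simulate -> fold-stats -> code -> search -> timeline.

Every stage is a pure function of (inputs, config, seed); a run manifest
records package version, seeds, parameters and the SHA-256 checksum of
every artifact, so repeated runs can be compared checksum-for-checksum.
All randomness flows from the single global seed through named substreams
(one per stage), derived by hashing the stage name into a 31-bit offset.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import __version__
from .chronology import (
    anchor_substructures,
    apply_clock,
    calibrate_clock,
    read_calibration_tsv,
    read_interactions_tsv,
)
from .coding import attach_ancestor, build_matrix, code_abundance, read_census_tsv, to_nexus
from .folding import EnergyModel, mfe_structure, morphospace_stats, partition_bpp
from .parsimony import (
    BNB_TAXA_CAP,
    HEURISTIC_RESTARTS_LARGE,
    ParsimonyResult,
    branch_and_bound,
    fit_stats,
    heuristic_search,
    node_distances,
    to_newick,
)
from .structure import CloverleafTemplate, read_fasta, write_fasta
from .synthetic import (
    SCAFFOLD_STRUCTURE,
    SimulationConfig,
    evolve_trna_family,
    simulate_domain_census,
    simulate_reference_tree,
)

log = logging.getLogger("retrodict")

ALL_STAGES = ("simulate", "fold-stats", "code", "tom", "tos", "tod", "timeline")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending input."""


@dataclass
class RunConfig:
    """Global pipeline configuration (JSON-serialisable)."""

    out_dir: str = "run"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    # simulation block
    n_taxa: int = 8
    simulation: dict = field(default_factory=dict)
    # folding block
    energy_model: dict = field(default_factory=dict)
    # coding block
    k_states: int = 24
    # search block
    force_bnb: bool = False
    g1_samples: int = 10_000
    heuristic_restarts: int = HEURISTIC_RESTARTS_LARGE
    # chronology block
    calibration_tsv: str | None = None
    interactions_tsv: str | None = None

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise PipelineError(f"unknown config fields: {sorted(unknown)}")
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(**data)


def _substream(seed: int, stage: str) -> int:
    return (seed * 1000003 + zlib.crc32(stage.encode())) % (2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(path: Path, text: str, manifest: dict) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(text)
    manifest["artifacts"][path.name] = _sha256(path)


def compute_stats_table(
    sequences: Mapping[str, str],
    model: EnergyModel | None = None,
    template: CloverleafTemplate | None = None,
) -> pd.DataFrame:
    """Long-format table (name, region, stat, value) for every molecule.

    Statistics are computed for the whole molecule (region ``all``) and
    restricted to each cloverleaf region of the template.
    """
    model = model or EnergyModel()
    template = template or CloverleafTemplate()
    rows: list[dict] = []
    for name in sorted(sequences):
        seq = sequences[name]
        bpm = partition_bpp(seq, model)
        mfe = mfe_structure(seq, model, name=name)
        regions: dict[str, set[int] | None] = {"all": None}
        if template.max_index() <= len(seq):
            for region in template.regions:
                regions[region] = template.indices(region)
        for region, idx in regions.items():
            st = morphospace_stats(seq, model, indices=idx, bpm=bpm, mfe=mfe)
            for stat, value in (("Q", st.Q), ("P", st.P), ("S", st.S)):
                rows.append(
                    {"name": name, "region": region, "stat": stat, "value": value}
                )
    return pd.DataFrame(rows)


#: Exact (branch-and-bound) search is the pipeline default up to this many
#: taxa; beyond it the heuristic with random-addition restarts takes over
#: unless branch and bound is explicitly forced.
EXACT_SEARCH_DEFAULT_CAP = 12


def _search(matrix, cfg: RunConfig, stage: str) -> ParsimonyResult:
    n = len(matrix.taxa)
    seed = _substream(cfg.seed, stage)
    if cfg.force_bnb:
        return branch_and_bound(matrix, taxa_cap=BNB_TAXA_CAP, seed=seed)
    if n <= EXACT_SEARCH_DEFAULT_CAP:
        return branch_and_bound(matrix, seed=seed)
    return heuristic_search(matrix, seed=seed, restarts=cfg.heuristic_restarts)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the selected stages; returns the run manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "version": __version__,
        "seed": cfg.seed,
        "stages": list(cfg.stages),
        "config": dataclasses.asdict(cfg),
        "artifacts": {},
    }
    model = EnergyModel(**cfg.energy_model) if cfg.energy_model else EnergyModel()
    state: dict[str, Any] = {}

    for stage in cfg.stages:
        log.info("stage %s", stage)
        try:
            if stage == "simulate":
                sim = SimulationConfig(
                    n_taxa=cfg.n_taxa,
                    seed=_substream(cfg.seed, "simulate"),
                    **cfg.simulation,
                )
                tree = simulate_reference_tree(sim.n_taxa, sim.seed)
                seqs = evolve_trna_family(tree, sim)
                truth = simulate_domain_census(tree, sim)
                state["tree_true"] = tree
                state["sequences"] = seqs
                state["census_truth"] = truth
                _write(out / "family.fasta", write_fasta(seqs), manifest)
                _write(
                    out / "family.dbn",
                    "".join(
                        f">{n}\n{s}\n{SCAFFOLD_STRUCTURE}\n"
                        for n, s in sorted(seqs.items())
                    ),
                    manifest,
                )
                _write(out / "true_tree.nwk", to_newick(tree) + "\n", manifest)
                _write(
                    out / "census.tsv",
                    truth.census.to_csv(sep="\t", index_label="domain"),
                    manifest,
                )
                _write(
                    out / "true_domain_ages.tsv",
                    "domain\tage_gy\n"
                    + "".join(f"{d}\t{a:.4f}\n" for d, a in sorted(truth.ages.items())),
                    manifest,
                )
                _write(
                    out / "interactions.tsv",
                    "domain_id\tsubstructure\tevidence\n"
                    + "".join(
                        f"{r.domain}\t{r.substructure}\tsimulated\n"
                        for r in truth.interactions
                    ),
                    manifest,
                )
            elif stage == "fold-stats":
                seqs = state.get("sequences")
                if seqs is None:
                    fasta = out / "family.fasta"
                    if not fasta.exists():
                        raise PipelineError("fold-stats: no sequences (run simulate first)")
                    seqs = read_fasta(fasta.read_text())
                    state["sequences"] = seqs
                stats = compute_stats_table(seqs, model)
                state["stats"] = stats
                _write(out / "morphospace.tsv", stats.to_csv(sep="\t", index=False), manifest)
            elif stage == "code":
                stats = state.get("stats")
                if stats is None:
                    raise PipelineError("code: no stats table (run fold-stats first)")
                regional = stats[stats["region"] != "all"]
                tom = attach_ancestor(build_matrix(regional, mode="ToM", k=cfg.k_states))
                tos = attach_ancestor(
                    build_matrix(regional, mode="ToS", k=cfg.k_states, stat="Q")
                )
                state["tom_matrix"] = tom
                state["tos_matrix"] = tos
                _write(out / "tom_matrix.nex", to_nexus(tom), manifest)
                _write(out / "tos_matrix.nex", to_nexus(tos), manifest)
            elif stage == "tom":
                matrix = state.get("tom_matrix")
                if matrix is None:
                    raise PipelineError("tom: no character matrix (run code first)")
                res = _search(matrix, cfg, "tom")
                st = fit_stats(
                    res.best,
                    matrix,
                    g1_samples=cfg.g1_samples,
                    seed=_substream(cfg.seed, "g1-tom"),
                )
                res.stats = st
                state["tom_result"] = res
                _write(out / "tom.nwk", to_newick(res.best) + "\n", manifest)
                _write(
                    out / "tom_fitstats.json",
                    json.dumps(
                        {
                            **st.as_dict(),
                            "method": res.method,
                            "seed": res.seed,
                            "trees_examined": res.trees_examined,
                            "n_optimal_trees": len(res.trees),
                        },
                        indent=2,
                    )
                    + "\n",
                    manifest,
                )
            elif stage == "tos":
                matrix = state.get("tos_matrix")
                if matrix is None:
                    raise PipelineError("tos: no character matrix (run code first)")
                res = _search(matrix, cfg, "tos")
                st = fit_stats(
                    res.best,
                    matrix,
                    g1_samples=cfg.g1_samples,
                    seed=_substream(cfg.seed, "g1-tos"),
                )
                res.stats = st
                state["tos_result"] = res
                _write(out / "tos.nwk", to_newick(res.best) + "\n", manifest)
                _write(
                    out / "tos_fitstats.json",
                    json.dumps(
                        {**st.as_dict(), "method": res.method, "seed": res.seed},
                        indent=2,
                    )
                    + "\n",
                    manifest,
                )
            elif stage == "tod":
                truth = state.get("census_truth")
                if truth is not None:
                    census = truth.census
                else:
                    path = out / "census.tsv"
                    if not path.exists():
                        raise PipelineError("tod: no census (run simulate first)")
                    census = read_census_tsv(path)
                tod_matrix = attach_ancestor(code_abundance(census, k=cfg.k_states))
                res = _search(tod_matrix, cfg, "tod")
                state["tod_result"] = res
                state["tod_matrix"] = tod_matrix
                _write(out / "tod.nwk", to_newick(res.best) + "\n", manifest)
            elif stage == "timeline":
                res = state.get("tod_result")
                if res is None:
                    raise PipelineError("timeline: no domain tree (run tod first)")
                nd = node_distances(res.best)
                if cfg.calibration_tsv:
                    points = read_calibration_tsv(cfg.calibration_tsv)
                else:
                    # default calibration: most basal = root age, tips = 0
                    truth = state.get("census_truth")
                    if truth is None:
                        raise PipelineError(
                            "timeline: calibration_tsv missing and no simulated truth"
                        )
                    rel = nd["relative_age"]
                    points = [
                        (rel[d], truth.ages[d]) for d in rel if d in truth.ages
                    ]
                clock = calibrate_clock(points)
                domain_tl = apply_clock(clock, nd["relative_age"])
                if cfg.interactions_tsv:
                    interactions = read_interactions_tsv(cfg.interactions_tsv)
                else:
                    truth = state.get("census_truth")
                    interactions = truth.interactions if truth else []
                sub_tl = anchor_substructures(domain_tl, interactions)
                _write(out / "timeline_domains.tsv", domain_tl.to_tsv(), manifest)
                _write(out / "timeline_substructures.tsv", sub_tl.to_tsv(), manifest)
                _write(
                    out / "clock.json",
                    json.dumps(
                        {
                            "slope": clock.slope,
                            "intercept": clock.intercept,
                            "r_squared": clock.r_squared,
                            "n_points": len(clock.points),
                        },
                        indent=2,
                    )
                    + "\n",
                    manifest,
                )
            else:
                raise PipelineError(f"unknown stage {stage!r}")
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage {stage} failed: {exc}") from exc

    _write(out / "manifest.json", json.dumps(manifest, indent=2, sort_keys=True) + "\n", manifest)
    # manifest checksum of itself is meaningless; drop it
    manifest["artifacts"].pop("manifest.json", None)
    return manifest
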