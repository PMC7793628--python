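"""Run configuration and end-to-end pipeline orchestration.

Stages: homoplasy partitioning (implied-weights search), MCMC over tree
+ homology space, majority-rule consensus, ancestral-state summaries and
phenetic distances.  Every stage is reproducible from the config plus a
seed; a manifest records seeds and output checksums.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import numpy as np
import yaml

from . import __version__
from .ancestors import AncestorSample, ancestral_state_posteriors, \
    sample_ancestral_states
from .matrix import (HomologyBlock, MorphMatrix, PartitionScheme,
                     partition_characters, read_nexus, split_homology,
                     write_nexus)
from .mcmc import (McmcConfig, McmcResult, ModelState, majority_rule_consensus,
                   consensus_newick, run_mcmc)
from .mk import MkPartitionModel
from .parsimony import ParsimonyConfig, homology_min_homoplasy, \
    implied_weights_search
from .phenetics import ancestor_row, distance_matrix, matrix_distance, \
    nearest_taxon, pco, subsample_ancestors
from .priors import FBDParams, FossilSite, PriorConfig, RelaxedClock, \
    SiteAgeParams
from .tree import TimeTree, build_initial_tree


@dataclass
class RunConfig:
    """Structured run settings (parsed from a YAML file)."""

    matrix_path: Optional[str] = None
    blocks: Dict[str, List[List[int]]] = field(default_factory=dict)
    sites: List[FossilSite] = field(default_factory=list)
    constraints: List[List[str]] = field(default_factory=list)
    groups: Dict[str, str] = field(default_factory=dict)
    focal_clade: List[str] = field(default_factory=list)
    chain_length: int = 100_000
    sample_every: int = 100
    burnin_fraction: float = 0.1
    n_runs: int = 1
    seed: int = 1
    mkv: bool = False
    rho: float = 0.0
    default_tip_age: float = 0.0
    concavity: float = 10.0
    priors: PriorConfig = field(default_factory=PriorConfig)

    def __post_init__(self) -> None:
        if not 0 <= self.burnin_fraction < 1:
            raise ValueError("burn-in fraction must lie in [0, 1)")
        if self.chain_length % self.sample_every:
            raise ValueError("chain length must be divisible by sample interval")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sites = [FossilSite(name=s["name"], min_age=float(s["min_age"]),
                            max_age=float(s["max_age"]),
                            taxa=list(s["taxa"]))
                 for s in raw.pop("sites", [])]
        priors = PriorConfig(**raw.pop("priors", {}))
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(sites=sites, priors=priors, **raw)


# ---------------------------------------------------------------------------
# Partitioning stage
# ---------------------------------------------------------------------------

@dataclass
class PartitionResult:
    scheme: PartitionScheme
    homoplasy: np.ndarray          # per composite character (min rule applied)
    state_counts: List[int]
    search_newick: str
    search_score: float


def compute_partition_scheme(fixed: MorphMatrix,
                             blocks: Sequence[HomologyBlock],
                             config: Optional[ParsimonyConfig] = None
                             ) -> PartitionResult:
    """Homoplasy-based partition scheme for the composite matrix.

    A single implied-weights search is run on the matrix containing the
    fixed columns plus every coding of every block; block characters
    whose homoplasy differs between homology states are assigned the
    lower value, and their observed-state count is taken from the
    lower-homoplasy coding.
    """
    config = config or ParsimonyConfig()
    search_matrix = fixed
    for block in blocks:
        for coding in block.codings:
            search_matrix = search_matrix.concat(coding)
    result = implied_weights_search(search_matrix, config)
    n_fixed = fixed.n_char
    homoplasy = list(result.homoplasy[:n_fixed])
    state_counts = [fixed.state_count(j) for j in range(n_fixed)]
    offset = n_fixed
    for block in blocks:
        w = block.n_char
        vectors = []
        for _ in range(block.state_count):
            vectors.append(result.homoplasy[offset: offset + w])
            offset += w
        mins = homology_min_homoplasy(block, vectors)
        argmin = np.vstack(vectors).argmin(axis=0)
        homoplasy.extend(int(m) for m in mins)
        state_counts.extend(
            block.codings[int(argmin[i])].state_count(i) for i in range(w))
    scheme = partition_characters(state_counts, [int(h) for h in homoplasy])
    return PartitionResult(scheme=scheme, homoplasy=np.array(homoplasy),
                           state_counts=state_counts,
                           search_newick=result.newick,
                           search_score=result.score)


# ---------------------------------------------------------------------------
# State construction
# ---------------------------------------------------------------------------

def make_model_state(fixed: MorphMatrix, blocks: Sequence[HomologyBlock],
                     scheme: PartitionScheme, config: RunConfig,
                     rng: Optional[np.random.Generator] = None,
                     sample_from_prior: bool = False,
                     include_tree_prior: bool = True) -> ModelState:
    """Prior-compatible initial state for the sampler."""
    rng = rng or np.random.default_rng(config.seed)
    site_ages = SiteAgeParams(sites=list(config.sites))
    tip_ages = {}
    for taxon in fixed.taxa:
        age = site_ages.tip_age(taxon)
        tip_ages[taxon] = config.default_tip_age if age is None else age
    constraints = [frozenset(c) for c in config.constraints]
    tree = build_initial_tree(tip_ages, constraints, rng)
    priors = config.priors
    fbd = FBDParams(
        birth=priors.birth_real_space_mean,
        death=priors.death_mean,
        sampling=priors.sampling_mean,
        origin=min(tree.root.age + 20.0, priors.origin_max),
        rho=config.rho,
    )
    clock = RelaxedClock(clock_rate=math.exp(priors.clock_log_mean),
                         sigma=0.5)
    model = MkPartitionModel.flat(scheme)
    return ModelState(
        tree=tree, fixed=fixed, blocks=list(blocks), scheme=scheme,
        partition_model=model, clock=clock, fbd=fbd, site_ages=site_ages,
        priors=priors, constraints=constraints, mkv=config.mkv,
        sample_from_prior=sample_from_prior,
        include_tree_prior=include_tree_prior,
    )


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def pipeline_all(fixed: MorphMatrix, blocks: Sequence[HomologyBlock],
                 config: RunConfig, outdir) -> Dict[str, object]:
    """Partition, sample, summarise; returns the manifest dictionary."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: Dict[str, object] = {
        "version": __version__,
        "seed": config.seed,
        "chain_length": config.chain_length,
        "sample_every": config.sample_every,
        "burnin_fraction": config.burnin_fraction,
        "stages": [],
        "checksums": {},
    }

    def fail(stage: str, exc: Exception):
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    # -- partitioning --
    try:
        part = compute_partition_scheme(
            fixed, blocks, ParsimonyConfig(concavity=config.concavity,
                                           seed=config.seed))
    except Exception as exc:
        fail("partition", exc)
    part_rows = ["char\tpartition\tstate_count\thomoplasy"]
    for j, pid in enumerate(part.scheme.assignment):
        sc, hp = part.scheme.key[pid]
        part_rows.append(f"{j + 1}\t{pid}\t{sc}\t{hp}")
    (out / "partitions.tsv").write_text("\n".join(part_rows) + "\n")
    (out / "parsimony_tree.nwk").write_text(part.search_newick + "\n")
    manifest["stages"].append("partition")

    # -- MCMC --
    focal = list(config.focal_clade)
    ancestors: List[AncestorSample] = []
    anc_rng = np.random.default_rng(config.seed + 10_007)

    def callback(gen: int, state: ModelState):
        if focal:
            ancestors.append(sample_ancestral_states(
                state, focal, anc_rng, generation=gen))

    try:
        state = make_model_state(fixed, blocks, part.scheme, config)
        mcfg = McmcConfig(chain_length=config.chain_length,
                          sample_every=config.sample_every,
                          burnin_fraction=config.burnin_fraction,
                          seed=config.seed)
        result = run_mcmc(state, mcfg, sample_callback=callback)
    except Exception as exc:
        fail("mcmc", exc)
    result.trace.to_csv(out / "trace.tsv", sep="\t", index=False)
    (out / "trees.nwk").write_text("\n".join(result.trees) + "\n")
    if blocks:
        hdf = result.trace[["generation"]].copy()
        hdf["h"] = result.homology_trace.states
        lls = np.vstack(result.homology_trace.state_logliks)
        for h in range(lls.shape[1]):
            hdf[f"ll_h{h}"] = lls[:, h]
        hdf.to_csv(out / "homology.tsv", sep="\t", index=False)
    manifest["stages"].append("mcmc")

    # -- consensus --
    try:
        retained = result.retained_trees()
        cons = majority_rule_consensus(retained)
        (out / "consensus.nwk").write_text(consensus_newick(cons) + "\n")
    except Exception as exc:
        fail("consensus", exc)
    manifest["stages"].append("consensus")

    # -- ancestors --
    discard = len(ancestors) - len(retained)
    kept_ancestors = ancestors[discard:] if focal else []
    if kept_ancestors:
        try:
            summary = ancestral_state_posteriors(kept_ancestors)
            rows = ["character\tmodal_state\tposterior_probability"]
            for rec in summary:
                rows.append(f"{rec['character'] + 1}\t{rec['modal_state']}\t"
                            f"{rec['posterior_probability']:.4f}")
            (out / "ancestors_summary.tsv").write_text("\n".join(rows) + "\n")
            anc_rows = ["generation\th\tstates"]
            for s in kept_ancestors:
                anc_rows.append(
                    f"{s.generation}\t{','.join(map(str, s.homology))}\t"
                    + "".join("?" if x < 0 else str(x) for x in s.states))
            (out / "ancestors.tsv").write_text("\n".join(anc_rows) + "\n")
        except Exception as exc:
            fail("ancestors", exc)
        manifest["stages"].append("ancestors")

    # -- phenetics --
    if kept_ancestors:
        try:
            from .matrix import compose_matrix_multi

            sub, info = subsample_ancestors(kept_ancestors)
            modal_h = sub[0].homology if sub else tuple([0] * len(blocks))
            composite = compose_matrix_multi(fixed, blocks, list(modal_h))
            rows = list(composite.cells)
            labels = list(composite.taxa)
            for i, s in enumerate(sub):
                rows.append(ancestor_row(s.states))
                labels.append(f"ancestor_{i}")
            dm = distance_matrix(rows, labels)
            dm.to_frame().to_csv(out / "distances.tsv", sep="\t", index=False)
            nearest_rows = ["generation\tnearest\tdistance\tgroup\ttied"]
            for s in kept_ancestors:
                composite_s = compose_matrix_multi(fixed, blocks,
                                                   list(s.homology))
                near = nearest_taxon(ancestor_row(s.states), composite_s)
                group = config.groups.get(near.label, "")
                nearest_rows.append(
                    f"{s.generation}\t{near.label}\t{near.distance:.4f}\t"
                    f"{group}\t{int(near.tied)}")
            (out / "nearest.tsv").write_text("\n".join(nearest_rows) + "\n")
            manifest["subsample"] = info
        except Exception as exc:
            fail("phenetics", exc)
        manifest["stages"].append("phenetics")

    for f in sorted(out.iterdir()):
        if f.name != "manifest.json" and f.is_file():
            manifest["checksums"][f.name] = _sha256(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def load_data(config: RunConfig) -> Tuple[MorphMatrix, List[HomologyBlock]]:
    """Read the NEXUS matrix and split out declared homology blocks."""
    if not config.matrix_path:
        raise ValueError("config has no matrix_path")
    full = read_nexus(config.matrix_path)
    return split_homology(full, config.blocks)
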