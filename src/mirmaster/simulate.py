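"""Synthetic paired gene/miRNA expression studies with planted regulation.

The generator emulates the structure of a three-condition liver study
(lean reference, obesogenic diet with an oleic-acid lineage, obesogenic
diet with an EPA lineage): quantile-normalized log2 expression for genes
and miRNAs over n = 9/8/7 samples, a set of differentially expressed
features shared by the two high-fat conditions, and planted repressive
miRNA -> gene regulations whose targets owe their differential expression
entirely to the shift of their regulator.  Everything is generated directly
on the normalized log2 scale and the full ground truth is recorded for
parameter-recovery benchmarks.

Construction of a planted pair (within one condition):

    mirna  = mu_m + s * d_m * c + eps_m,   eps_m ~ N(0, noise_sd^2)
    gene   = mu_g - b * (mirna - mu_m) + eps_g

where ``c`` indicates the high-fat conditions, ``d_m`` is the regulator's
direction (opposite to its target's) and the slope ``b`` is scaled so the
regulator explains ``repression_strength`` of the target's within-condition
variance:  b = sqrt(r / (1 - r)) * noise_sd / sigma_m.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .containers import (
    CONDITIONS,
    DEFAULT_CONTRASTS,
    ExpressionStudy,
    GeneSetCollection,
    PlantedTruth,
    ReactionMapping,
    TargetDatabaseSet,
)

DB_SOURCES = ("dbA", "dbB", "dbC")


def _default_samples() -> dict[str, int]:
    return {"reference": 9, "HFoleic": 8, "HFepa": 7}


@dataclass
class SimulationConfig:
    n_genes: int = 500
    n_mirnas: int = 60
    samples_per_condition: dict[str, int] = field(default_factory=_default_samples)
    n_planted_regulations: int = 40
    #: planted pairs are grouped: each regulator miRNA represses this many targets
    targets_per_regulator: int = 5
    #: log2 mean shift for directly condition-shifted DE features
    effect_size_de: float = 2.0
    #: log2 mean shift applied to planted regulator miRNAs (opposite to targets)
    mirna_de_shift: float = 1.4
    #: fraction of the target's within-condition variance explained by its regulator
    repression_strength: float = 0.8
    noise_sd: float = 0.5
    #: DE miRNAs with no planted targets (nulls challenging MMRA steps 2-3)
    n_null_de_mirnas: int = 6
    #: directly condition-shifted genes with no miRNA regulator (0 in the
    #: reference benchmark: such genes are confounded with every DE miRNA)
    n_extra_de_genes: int = 0
    db_overlap: float = 0.9
    #: expected spurious predictions per miRNA per source
    db_false_rate: float = 5.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0 or self.n_mirnas <= 0:
            raise ValueError("n_genes and n_mirnas must be positive")
        if set(self.samples_per_condition) != set(CONDITIONS):
            raise ValueError(f"conditions must be exactly {set(CONDITIONS)}")
        if any(n < 3 for n in self.samples_per_condition.values()):
            raise ValueError("samples_per_condition must be >= 3 (DE tests undefined below)")
        if not 0.0 <= self.repression_strength < 1.0:
            raise ValueError("repression_strength must be in [0, 1)")
        if not 0.0 <= self.db_overlap <= 1.0:
            raise ValueError("db_overlap must be in [0, 1]")
        if self.n_planted_regulations < 0 or self.db_false_rate < 0:
            raise ValueError("counts and rates must be non-negative")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.n_planted_regulations > 0:
            n_reg = math.ceil(self.n_planted_regulations / self.targets_per_regulator)
            if n_reg + self.n_null_de_mirnas > self.n_mirnas:
                raise ValueError("not enough miRNAs for the requested planted regulations")
            if self.n_planted_regulations + self.n_extra_de_genes > self.n_genes:
                raise ValueError("not enough genes for the requested planted regulations")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        return cls(**d)


#: a paper-scale preset mirroring the deposited arrays (tens of thousands of
#: gene probes, hundreds of miRNAs); not used by the test suite
PAPER_SCALE = dict(n_genes=60_000, n_mirnas=600, n_planted_regulations=400)


def _condition_vector(config: SimulationConfig) -> tuple[list[str], np.ndarray]:
    samples: list[str] = []
    indicator: list[float] = []
    for cond in CONDITIONS:
        n = config.samples_per_condition[cond]
        samples.extend(f"{cond}_{i + 1}" for i in range(n))
        indicator.extend([0.0 if cond == "reference" else 1.0] * n)
    return samples, np.asarray(indicator)


def generate_study(config: SimulationConfig) -> ExpressionStudy:
    """Generate a paired study with recorded :class:`PlantedTruth`.

    Identical seeds give bit-identical output.  Targets of planted pairs
    carry no direct condition term: their differential expression is
    inherited through the regulator, which reproduces the anti-correlated
    direction pattern (down genes regulated by up miRNAs and vice versa).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    samples, c = _condition_vector(config)
    n_samples = len(samples)

    gene_ids = [f"gene_{i:04d}" for i in range(config.n_genes)]
    mirna_ids = [f"mir_{i:03d}" for i in range(config.n_mirnas)]

    n_reg = (
        math.ceil(config.n_planted_regulations / config.targets_per_regulator)
        if config.n_planted_regulations
        else 0
    )
    mirna_perm = rng.permutation(config.n_mirnas)
    regulators = [mirna_ids[i] for i in mirna_perm[:n_reg]]
    null_de_mirnas = [mirna_ids[i] for i in mirna_perm[n_reg : n_reg + config.n_null_de_mirnas]]
    gene_perm = rng.permutation(config.n_genes)
    target_genes = [gene_ids[i] for i in gene_perm[: config.n_planted_regulations]]
    extra_de_genes = [
        gene_ids[i]
        for i in gene_perm[
            config.n_planted_regulations : config.n_planted_regulations + config.n_extra_de_genes
        ]
    ]

    # pair up: regulator r gets consecutive chunks of targets; direction
    # alternates so both signature sides are populated
    regulations: list[tuple[str, str]] = []
    mirna_dir = {m: (1.0 if k % 2 == 0 else -1.0) for k, m in enumerate(regulators)}
    for k, g in enumerate(target_genes):
        regulations.append((regulators[k // config.targets_per_regulator], g))
    for k, m in enumerate(null_de_mirnas):
        mirna_dir[m] = 1.0 if k % 2 == 0 else -1.0

    mirna_base = rng.uniform(4.0, 10.0, size=config.n_mirnas)
    gene_base = rng.uniform(6.0, 12.0, size=config.n_genes)

    mirna_mat = (
        mirna_base[:, None]
        + rng.normal(0.0, config.noise_sd, size=(config.n_mirnas, n_samples))
    )
    for m in list(mirna_dir):
        i = mirna_ids.index(m)
        mirna_mat[i] += mirna_dir[m] * config.mirna_de_shift * c

    gene_mat = (
        gene_base[:, None] + rng.normal(0.0, config.noise_sd, size=(config.n_genes, n_samples))
    )
    r = config.repression_strength
    slope = math.sqrt(r / (1.0 - r)) if r > 0 else 0.0  # sigma_m == noise_sd cancels
    for m, g in regulations:
        gi, mi = gene_ids.index(g), mirna_ids.index(m)
        gene_mat[gi] -= slope * (mirna_mat[mi] - mirna_base[mi])
    for k, g in enumerate(extra_de_genes):
        gi = gene_ids.index(g)
        gene_mat[gi] += (1.0 if k % 2 == 0 else -1.0) * config.effect_size_de * c

    # record truth: target direction is opposite to its regulator's shift
    up_g = {g for m, g in regulations if mirna_dir[m] < 0}
    down_g = {g for m, g in regulations if mirna_dir[m] > 0}
    up_g |= {g for k, g in enumerate(extra_de_genes) if k % 2 == 0}
    down_g |= {g for k, g in enumerate(extra_de_genes) if k % 2 == 1}
    up_m = {m for m, d in mirna_dir.items() if d > 0}
    down_m = {m for m, d in mirna_dir.items() if d < 0}
    truth = PlantedTruth(
        regulations={(m, g, "repressive") for m, g in regulations},
        de_genes={k: (set(up_g), set(down_g)) for k in DEFAULT_CONTRASTS},
        de_mirnas={k: (set(up_m), set(down_m)) for k in DEFAULT_CONTRASTS},
    )

    study = ExpressionStudy(
        gene_matrix=pd.DataFrame(gene_mat, index=gene_ids, columns=samples),
        mirna_matrix=pd.DataFrame(mirna_mat, index=mirna_ids, columns=samples),
        annotation=pd.Series(
            [s.rsplit("_", 1)[0] for s in samples], index=samples, name="condition"
        ),
        truth=truth,
    )
    study.validate()
    return study


def generate_target_databases(
    truth: PlantedTruth, config: SimulationConfig
) -> TargetDatabaseSet:
    """Three mock prediction sources covering the planted regulations.

    Each true pair enters each source independently with probability
    ``db_overlap``; each source additionally reports Poisson(``db_false_rate``)
    spurious targets per miRNA, drawn from the non-target genes.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 1])
    gene_ids = [f"gene_{i:04d}" for i in range(config.n_genes)]
    mirna_ids = [f"mir_{i:03d}" for i in range(config.n_mirnas)]
    true_targets: dict[str, set[str]] = {}
    for m, g, _sign in sorted(truth.regulations):
        true_targets.setdefault(m, set()).add(g)

    sources: dict[str, dict[str, set[str]]] = {}
    for source in DB_SOURCES:
        per_mirna: dict[str, set[str]] = {}
        for m in mirna_ids:
            hits = {
                g for g in sorted(true_targets.get(m, ())) if rng.random() < config.db_overlap
            }
            n_false = rng.poisson(config.db_false_rate)
            if n_false:
                pool = [g for g in gene_ids if g not in true_targets.get(m, ())]
                picks = rng.choice(len(pool), size=min(n_false, len(pool)), replace=False)
                hits |= {pool[i] for i in picks}
            if hits:
                per_mirna[m] = hits
        sources[source] = per_mirna
    return TargetDatabaseSet(sources=sources)


def generate_pathways_and_reactions(
    study: ExpressionStudy,
    config: SimulationConfig,
    *,
    n_enriched: int = 3,
    n_null: int = 5,
    pathway_size: int = 25,
    enriched_de_fraction: float = 0.8,
    reactions_per_gene: tuple[int, int] = (1, 3),
) -> tuple[GeneSetCollection, ReactionMapping]:
    """Mock pathway gene sets and a gene->reaction->pathway mapping.

    Enriched pathways draw ``enriched_de_fraction`` of their members from the
    planted up-regulated genes (recorded as truly enriched); null pathways are
    random samples of non-DE genes.
    """
    if pathway_size > config.n_genes:
        raise ValueError("pathway_size exceeds the gene universe")
    rng = np.random.default_rng([config.seed, 2])
    gene_ids = list(study.gene_matrix.index)
    truth = study.truth
    de_up: list[str] = []
    de_all: set[str] = set()
    if truth is not None and truth.de_genes:
        up, down = next(iter(truth.de_genes.values()))
        de_up = sorted(up)
        de_all = up | down
    non_de = [g for g in gene_ids if g not in de_all]

    sets: dict[str, set[str]] = {}
    truly: set[str] = set()
    for k in range(n_enriched):
        n_de = int(round(enriched_de_fraction * pathway_size))
        n_de = min(n_de, len(de_up))
        members = set(
            rng.choice(de_up, size=n_de, replace=False) if n_de else []
        )
        fill = rng.choice(non_de, size=pathway_size - len(members), replace=False)
        members |= set(fill)
        name = f"enriched_pathway_{k + 1}"
        sets[name] = members
        if n_de:
            truly.add(name)
    for k in range(n_null):
        members = set(rng.choice(non_de, size=min(pathway_size, len(non_de)), replace=False))
        sets[f"null_pathway_{k + 1}"] = members

    gene_to_reactions: dict[str, set[str]] = {}
    reaction_to_pathway: dict[str, str] = {}
    lo, hi = reactions_per_gene
    for name, members in sets.items():
        n_rxn = max(1, pathway_size // 2)
        rxns = [f"R_{name}_{i + 1}" for i in range(n_rxn)]
        for r in rxns:
            reaction_to_pathway[r] = name
        for g in sorted(members):
            k = int(rng.integers(lo, hi + 1))
            picks = rng.choice(n_rxn, size=min(k, n_rxn), replace=False)
            gene_to_reactions.setdefault(g, set()).update(rxns[i] for i in picks)

    collection = GeneSetCollection(sets=sets, truly_enriched=truly)
    mapping = ReactionMapping(
        gene_to_reactions=gene_to_reactions,
        reaction_to_pathway=reaction_to_pathway,
        truly_enriched_pathways=set(truly),
    )
    return collection, mapping
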