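"""Shared in-memory containers used across the pipeline stages.

Expression matrices are plain :class:`pandas.DataFrame` objects
(rows = features, columns = samples, values on the log2 scale); the
dataclasses here bundle them with annotations and recorded ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

CONDITIONS = ("reference", "HFoleic", "HFepa")

#: contrasts of interest, ``<group1>_vs_<group2>`` (log2fc = group1 - group2)
DEFAULT_CONTRASTS = ("HFoleic_vs_reference", "HFepa_vs_reference")


def parse_contrast(contrast: str) -> tuple[str, str]:
    """Split ``"A_vs_B"`` into ``("A", "B")``; raise on malformed names."""
    parts = contrast.split("_vs_")
    if len(parts) != 2 or not all(parts):
        raise ValueError(f"malformed contrast name {contrast!r}; expected '<group1>_vs_<group2>'")
    return parts[0], parts[1]


@dataclass
class PlantedTruth:
    """Ground truth recorded by the simulator for recovery benchmarks."""

    #: set of (mirna_id, gene_id, sign); sign is "repressive" for planted pairs
    regulations: set[tuple[str, str, str]] = field(default_factory=set)
    #: contrast -> (up gene set, down gene set)
    de_genes: dict[str, tuple[set[str], set[str]]] = field(default_factory=dict)
    #: contrast -> (up miRNA set, down miRNA set)
    de_mirnas: dict[str, tuple[set[str], set[str]]] = field(default_factory=dict)

    @property
    def pairs(self) -> set[tuple[str, str]]:
        return {(m, g) for m, g, _ in self.regulations}


@dataclass
class ExpressionStudy:
    """Paired gene/miRNA log2 matrices plus sample condition labels."""

    gene_matrix: pd.DataFrame
    mirna_matrix: pd.DataFrame
    #: sample id -> condition label
    annotation: pd.Series
    truth: PlantedTruth | None = None

    def samples_for(self, condition: str) -> list[str]:
        if condition not in set(self.annotation):
            raise ValueError(f"unknown condition {condition!r}")
        return list(self.annotation.index[self.annotation == condition])

    def validate(self) -> None:
        if list(self.gene_matrix.columns) != list(self.mirna_matrix.columns):
            raise ValueError("gene and miRNA matrices must share identical sample ordering")
        if list(self.gene_matrix.columns) != list(self.annotation.index):
            raise ValueError("annotation must cover the matrix samples in order")
        for name, m in (("gene", self.gene_matrix), ("mirna", self.mirna_matrix)):
            arr = m.to_numpy()
            if not pd.notna(arr).all():
                raise ValueError(f"{name} matrix contains missing values")


@dataclass(frozen=True)
class Signature:
    """Up/down differentially expressed gene sets of one contrast."""

    contrast: str
    up: frozenset[str]
    down: frozenset[str]

    def __post_init__(self) -> None:
        if self.up & self.down:
            raise ValueError("up and down signature sets must be disjoint")

    @property
    def genes(self) -> frozenset[str]:
        return self.up | self.down


@dataclass
class TargetDatabaseSet:
    """Per-source miRNA -> target-gene-set predictions."""

    #: source name -> (mirna id -> set of gene ids)
    sources: dict[str, dict[str, set[str]]]

    def consensus(self, min_sources: int = 2) -> dict[str, set[str]]:
        """Pairs predicted by at least ``min_sources`` distinct sources."""
        if min_sources > len(self.sources):
            raise ValueError(
                f"min_sources={min_sources} exceeds the {len(self.sources)} available sources"
            )
        counts: dict[tuple[str, str], int] = {}
        for per_mirna in self.sources.values():
            for mirna, genes in per_mirna.items():
                for g in genes:
                    counts[(mirna, g)] = counts.get((mirna, g), 0) + 1
        out: dict[str, set[str]] = {}
        for (mirna, g), k in counts.items():
            if k >= min_sources:
                out.setdefault(mirna, set()).add(g)
        return out


@dataclass
class GeneSetCollection:
    """Named gene sets (pathways) with recorded truly-enriched names."""

    sets: dict[str, set[str]]
    truly_enriched: set[str] = field(default_factory=set)


@dataclass
class ReactionMapping:
    """Gene -> reaction (many-to-many) and reaction -> pathway maps."""

    gene_to_reactions: dict[str, set[str]]
    reaction_to_pathway: dict[str, str]
    truly_enriched_pathways: set[str] = field(default_factory=set)

    @property
    def reactions(self) -> set[str]:
        return set(self.reaction_to_pathway)
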