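"""MicroRNA Master Regulator Analysis: steps 2-4 and the full pipeline.

Four sequential filters progressively reduce the candidate miRNA set:

1. differential expression (``diffexpr.mirna_differential_expression``);
2. consensus predicted targets (>= 2 of 3 sources) enriched in the up or
   down phenotype signature (one-sided Fisher, p < 0.05);
3. a mutual-information network built around each surviving miRNA (the
   miRNA is the only hub; edges to genes whose MI clears a null-calibrated
   significance threshold) enriched in the signature (Fisher, p < 0.05);
4. per signature gene, bidirectional stepwise OLS with AIC as the stop
   criterion over the miRNAs linked to the gene by network or databases;
   a (miRNA, gene) pair survives iff the miRNA is selected.

MI is estimated by equal-frequency binning of rank-transformed data with a
Miller-Madow bias correction; the significance threshold extrapolates an
exponential tail fitted to a permutation null, since direct permutation
cannot reach p = 1e-7 at n ~ 24.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionStudy, Signature, TargetDatabaseSet
from .diffexpr import (
    MirnaDECriteria,
    build_signature,
    de_mirna_sets,
    differential_expression,
    mirna_differential_expression,
)

logger = logging.getLogger(__name__)



# ---------------------------------------------------------------------------
# Fisher enrichment


@dataclass(frozen=True)
class FisherResult:
    mirna: str
    signature_side: str  # "up" | "down"
    table: tuple[int, int, int, int]  # overlap, targets-only, signature-only, neither
    p_value: float
    passed: bool


def _fisher_one_sided(overlap: int, n_targets: int, n_signature: int, n_universe: int) -> float:
    """P(X >= overlap) under the hypergeometric null (enrichment tail)."""
    return float(stats.hypergeom.sf(overlap - 1, n_universe, n_signature, n_targets))


def target_enrichment(
    mirna: str,
    targets: set[str],
    signature: Signature,
    universe: set[str],
    alpha: float = 0.05,
) -> tuple[FisherResult, FisherResult]:
    """One-sided Fisher enrichment of ``targets`` in each signature side."""
    if not universe:
        raise ValueError("empty universe")
    if not targets <= universe:
        raise ValueError("targets must be a subset of the universe")
    results = []
    for side, sig_genes in (("up", set(signature.up)), ("down", set(signature.down))):
        if not sig_genes <= universe:
            raise ValueError("signature genes must be a subset of the universe")
        a = len(targets & sig_genes)
        b = len(targets) - a
        c = len(sig_genes) - a
        d = len(universe) - a - b - c
        p = 1.0 if not targets else _fisher_one_sided(a, len(targets), len(sig_genes), len(universe))
        results.append(
            FisherResult(
                mirna=mirna,
                signature_side=side,
                table=(a, b, c, d),
                p_value=p,
                passed=bool(targets) and p < alpha,
            )
        )
    return results[0], results[1]


def consensus_targets(dbset: TargetDatabaseSet, min_sources: int = 2) -> dict[str, set[str]]:
    """miRNA -> genes predicted by at least ``min_sources`` sources."""
    return dbset.consensus(min_sources)


# ---------------------------------------------------------------------------
# Mutual information


def _n_bins(n: int) -> int:
    # n^0.4 grows the resolution with n while the expected joint-cell
    # occupancy n/k^2 = n^0.2 also grows, keeping the Miller-Madow
    # correction accurate at every scale
    return max(2, int(n**0.4))


def estimate_mi(
    x,
    y,
    estimator: str = "binned",
    n_bins: int | None = None,
    miller_madow: bool = True,
) -> float:
    """Mutual information in nats between two sample vectors.

    Default: equal-frequency binning of rank-transformed data into
    ``floor(n**0.4)`` bins per margin, Miller-Madow corrected and clipped
    at zero.  ``estimator="gaussian"`` gives the parametric
    -0.5*ln(1 - rho^2) alternative.  Constant vectors give 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = x.size
    if n < 8:
        raise ValueError("need at least 8 samples")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0
    if estimator == "gaussian":
        rho = np.corrcoef(x, y)[0, 1]
        rho = min(abs(rho), 1 - 1e-12)
        return -0.5 * math.log(1 - rho * rho)
    if estimator != "binned":
        raise ValueError(f"unknown estimator {estimator!r}")
    k = n_bins or _n_bins(n)
    rx = np.floor(stats.rankdata(x, method="ordinal") * k / (n + 1)).astype(int)
    ry = np.floor(stats.rankdata(y, method="ordinal") * k / (n + 1)).astype(int)
    joint = np.zeros((k, k))
    np.add.at(joint, (rx, ry), 1.0)
    pj = joint / n
    px = pj.sum(axis=1)
    py = pj.sum(axis=0)
    nz = pj > 0
    mi = float(np.sum(pj[nz] * np.log(pj[nz] / np.outer(px, py)[nz])))
    if miller_madow:
        kx = int((px > 0).sum())
        ky = int((py > 0).sum())
        kxy = int(nz.sum())
        mi -= (kxy - kx - ky + 1) / (2.0 * n)
    return max(mi, 0.0)


def mi_threshold(
    gene_matrix: pd.DataFrame,
    mirna_matrix: pd.DataFrame,
    p_target: float = 1e-7,
    n_perm: int = 2000,
    seed: int = 0,
    tail_fraction: float = 0.05,
    estimator: str = "binned",
) -> float:
    """MI value whose permutation-null exceedance probability is ``p_target``.

    Builds a null by permuting sample labels of randomly drawn miRNA rows
    against randomly drawn gene rows, then fits an exponential tail to the
    exceedances over the (1 - tail_fraction) null quantile and extrapolates.
    Deterministic under a fixed seed.
    """
    if not 0 < p_target <= 1:
        raise ValueError("p_target must be in (0, 1]")
    if p_target == 1.0:
        return 0.0
    if n_perm < 1000:
        raise ValueError(
            "n_perm must be >= 1000: the exponential tail fit needs at least "
            f"{int(1000 * tail_fraction)} exceedances to be stable"
        )
    rng = np.random.default_rng(seed)
    genes = gene_matrix.to_numpy(dtype=float)
    mirnas = mirna_matrix.to_numpy(dtype=float)
    null = np.empty(n_perm)
    for i in range(n_perm):
        g = genes[rng.integers(genes.shape[0])]
        m = rng.permutation(mirnas[rng.integers(mirnas.shape[0])])
        null[i] = estimate_mi(g, m, estimator=estimator)
    if p_target >= tail_fraction:
        return float(np.quantile(null, 1.0 - p_target))
    u = float(np.quantile(null, 1.0 - tail_fraction))
    exceedances = null[null > u] - u
    if exceedances.size < 20:
        raise ValueError(
            "too few null exceedances for a stable tail fit; increase n_perm "
            "or tail_fraction"
        )
    beta = float(exceedances.mean())
    return u + beta * math.log(tail_fraction / p_target)


@dataclass
class MINetwork:
    hub: str
    #: (gene id, mi estimate) for every gene whose MI clears the threshold
    edges: list[tuple[str, float]]
    threshold_mi: float

    @property
    def genes(self) -> set[str]:
        return {g for g, _ in self.edges}


def build_network(
    hub_mirna: str,
    gene_matrix: pd.DataFrame,
    mirna_matrix: pd.DataFrame,
    threshold_mi: float,
    estimator: str = "binned",
) -> MINetwork:
    """MI network around one miRNA hub; gene-gene edges are never computed."""
    if hub_mirna not in mirna_matrix.index:
        raise ValueError(f"unknown miRNA {hub_mirna!r}")
    m = mirna_matrix.loc[hub_mirna].to_numpy(dtype=float)
    edges = []
    for gene in gene_matrix.index:
        mi = estimate_mi(gene_matrix.loc[gene].to_numpy(dtype=float), m, estimator=estimator)
        if mi >= threshold_mi:
            edges.append((gene, mi))
    return MINetwork(hub=hub_mirna, edges=sorted(edges), threshold_mi=threshold_mi)


def network_enrichment(
    network: MINetwork, signature: Signature, universe: set[str], alpha: float = 0.05
) -> tuple[FisherResult, FisherResult]:
    """Fisher enrichment of the hub's network genes in the signature."""
    return target_enrichment(network.hub, network.genes & universe, signature, universe, alpha)


# ---------------------------------------------------------------------------
# Stepwise linear regression (AIC)


@dataclass
class SLRModel:
    gene: str
    candidate_mirnas: list[str]
    selected_mirnas: list[str]
    coefficients: dict[str, float]
    aic: float


def _ols_aic(y: np.ndarray, X: np.ndarray) -> tuple[float, np.ndarray]:
    n = y.size
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(np.sum((y - X @ coef) ** 2))
    rss = max(rss, 1e-300)
    k = X.shape[1]  # parameters including the intercept
    return n * math.log(rss / n) + 2 * k, coef


def stepwise_regression(
    gene_vector: pd.Series, candidate_mirna_matrix: pd.DataFrame
) -> SLRModel:
    """Bidirectional stepwise OLS from the intercept-only model.

    At each step the single variable addition or removal that most decreases
    AIC (= n*ln(RSS/n) + 2k, k counting the intercept) is applied; the search
    stops when no move decreases AIC.  Ties break by candidate id order.
    Zero-variance candidates are dropped with a warning; when the candidate
    count reaches n - 2, candidates are pre-ranked by |correlation| with the
    response and truncated to n - 3 for OLS identifiability.
    """
    y = gene_vector.to_numpy(dtype=float)
    n = y.size
    gene_name = str(gene_vector.name) if gene_vector.name is not None else "gene"
    candidates = sorted(str(c) for c in candidate_mirna_matrix.index)
    keep = []
    for c in candidates:
        if np.ptp(candidate_mirna_matrix.loc[c].to_numpy(dtype=float)) == 0:
            warnings.warn(f"dropping zero-variance candidate {c!r}")
        else:
            keep.append(c)
    candidates = keep
    if len(candidates) >= n - 2 and candidates:
        corr = {
            c: abs(np.corrcoef(y, candidate_mirna_matrix.loc[c].to_numpy(dtype=float))[0, 1])
            for c in candidates
        }
        candidates = sorted(
            sorted(candidates), key=lambda c: -corr[c]
        )[: max(n - 3, 1)]
        candidates = sorted(candidates)
        logger.warning(
            "gene %s: candidate count >= n-2, truncated to the %d strongest by |correlation|",
            gene_name,
            len(candidates),
        )

    data = {c: candidate_mirna_matrix.loc[c].to_numpy(dtype=float) for c in candidates}

    def design(sel: list[str]) -> np.ndarray:
        cols = [np.ones(n)] + [data[c] for c in sel]
        return np.column_stack(cols)

    selected: list[str] = []
    current_aic, coef = _ols_aic(y, design(selected))
    while True:
        best_aic = current_aic
        best_move: tuple[str, str] | None = None
        for c in candidates:  # additions, id order => deterministic tie-break
            if c in selected:
                continue
            aic, _ = _ols_aic(y, design(sorted(selected + [c])))
            if aic < best_aic - 1e-12:
                best_aic, best_move = aic, ("add", c)
        for c in selected:  # removals
            trial = [s for s in selected if s != c]
            aic, _ = _ols_aic(y, design(trial))
            if aic < best_aic - 1e-12:
                best_aic, best_move = aic, ("remove", c)
        if best_move is None:
            break
        op, c = best_move
        selected = sorted(selected + [c]) if op == "add" else [s for s in selected if s != c]
        current_aic = best_aic
    final_aic, coef = _ols_aic(y, design(selected))
    coefficients = {c: float(coef[i + 1]) for i, c in enumerate(selected)}
    return SLRModel(
        gene=gene_name,
        candidate_mirnas=candidates,
        selected_mirnas=selected,
        coefficients=coefficients,
        aic=final_aic,
    )


# ---------------------------------------------------------------------------
# The four-step pipeline


@dataclass
class MMRAConfig:
    mirna_criteria: MirnaDECriteria = field(default_factory=MirnaDECriteria)
    gene_alpha: float = 0.05  # FDR threshold of the gene signature
    fisher_alpha: float = 0.05  # steps 2 and 3
    mi_p_target: float = 1e-7  # genome-scale recommendation; desk scale uses 1e-3
    n_perm: int = 2000
    min_sources: int = 2
    estimator: str = "binned"
    test_method: str = "welch"
    seed: int = 0


#: preset for simulated desk-scale studies: expected false edges per hub
#: = mi_p_target * n_genes = 0.5 at the default 500-gene universe
def desk_scale_config(seed: int = 0) -> MMRAConfig:
    return MMRAConfig(mi_p_target=1e-3, seed=seed)


@dataclass
class MMRAResult:
    contrast: str
    #: surviving miRNA -> set of associated signature genes
    surviving: dict[str, set[str]]
    #: miRNA -> "step1" | "step2" | "step3" | "survived"
    audit: dict[str, str]
    #: per-step surviving candidate counts (steps 1..4)
    step_counts: list[int]
    signature: Signature
    networks: dict[str, MINetwork] = field(default_factory=dict)
    slr_models: dict[str, SLRModel] = field(default_factory=dict)
    mirna_de: pd.DataFrame | None = None
    gene_de: pd.DataFrame | None = None

    @property
    def pairs(self) -> set[tuple[str, str]]:
        return {(m, g) for m, genes in self.surviving.items() for g in genes}

    def to_table(self) -> pd.DataFrame:
        """Long-format table: gene, signature direction, miRNA, miRNA direction."""
        mirna_dir = {}
        if self.mirna_de is not None:
            mirna_dir = dict(zip(self.mirna_de["feature_id"], self.mirna_de["direction"]))
        rows = []
        for m, genes in sorted(self.surviving.items()):
            for g in sorted(genes):
                rows.append(
                    {
                        "gene": g,
                        "gene_signature": "up" if g in self.signature.up else "down",
                        "mirna": m,
                        "mirna_direction": mirna_dir.get(m, "n/a"),
                        "contrast": self.contrast,
                    }
                )
        return pd.DataFrame(rows, columns=["gene", "gene_signature", "mirna", "mirna_direction", "contrast"])


def run_mmra(
    study: ExpressionStudy,
    dbset: TargetDatabaseSet,
    contrast: str,
    config: MMRAConfig | None = None,
) -> MMRAResult:
    """Run the four sequential MMRA filters for one contrast."""
    config = config or MMRAConfig()
    universe = set(study.gene_matrix.index)

    gene_de = differential_expression(
        study.gene_matrix, study.annotation, contrast, method=config.test_method
    )
    signature = build_signature(gene_de, threshold=config.gene_alpha)

    # step 1: miRNA differential expression
    mirna_de = mirna_differential_expression(
        study.mirna_matrix, study.annotation, contrast, criteria=config.mirna_criteria,
        method=config.test_method,
    )
    up_m, down_m = de_mirna_sets(mirna_de)
    step1 = sorted(up_m | down_m)
    audit = {m: "step1" for m in study.mirna_matrix.index if m not in set(step1)}
    logger.info("%s step 1: %d DE miRNAs", contrast, len(step1))

    # step 2: consensus target enrichment in the signature
    consensus = consensus_targets(dbset, config.min_sources)
    step2 = []
    for m in step1:
        targets = consensus.get(m, set()) & universe
        r_up, r_down = target_enrichment(m, targets, signature, universe, config.fisher_alpha)
        if r_up.passed or r_down.passed:
            step2.append(m)
        else:
            audit[m] = "step2"
    logger.info("%s step 2: %d miRNAs with enriched consensus targets", contrast, len(step2))

    # step 3: MI network around each hub, enriched in the signature
    networks: dict[str, MINetwork] = {}
    step3 = []
    if step2:
        threshold = mi_threshold(
            study.gene_matrix,
            study.mirna_matrix,
            p_target=config.mi_p_target,
            n_perm=config.n_perm,
            seed=config.seed,
            estimator=config.estimator,
        )
        for m in step2:
            net = build_network(
                m, study.gene_matrix, study.mirna_matrix, threshold, estimator=config.estimator
            )
            networks[m] = net
            r_up, r_down = network_enrichment(net, signature, universe, config.fisher_alpha)
            if r_up.passed or r_down.passed:
                step3.append(m)
            else:
                audit[m] = "step3"
    logger.info("%s step 3: %d miRNAs with signature-enriched networks", contrast, len(step3))

    # step 4: stepwise regression per signature gene
    surviving: dict[str, set[str]] = {}
    slr_models: dict[str, SLRModel] = {}
    if step3:
        for gene in sorted(signature.genes):
            linked = [
                m
                for m in step3
                if gene in networks[m].genes or gene in consensus.get(m, set())
            ]
            if not linked:
                continue
            model = stepwise_regression(
                study.gene_matrix.loc[gene], study.mirna_matrix.loc[sorted(linked)]
            )
            slr_models[gene] = model
            for m in model.selected_mirnas:
                surviving.setdefault(m, set()).add(gene)
    for m in step3:
        audit[m] = "survived" if m in surviving else "step4"
    step4 = sorted(surviving)
    logger.info("%s step 4: %d miRNAs selected by stepwise regression", contrast, len(step4))

    return MMRAResult(
        contrast=contrast,
        surviving=surviving,
        audit=audit,
        step_counts=[len(step1), len(step2), len(step3), len(step4)],
        signature=signature,
        networks=networks,
        slr_models=slr_models,
        mirna_de=mirna_de,
        gene_de=gene_de,
    )
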