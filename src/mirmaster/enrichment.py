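"""Gene-set and metabolic-reaction enrichment.

Two complementary analyses:

* unweighted GSEA on a fold-change-ranked gene list: a two-sample
  Kolmogorov-Smirnov test between the rank positions of in-set and
  out-of-set genes, asking whether the set accumulates at the top
  (over-expressed) or bottom (under-expressed) of the list, with
  Benjamini-Yekutieli adjustment across sets;
* mapping of DE genes onto a gene -> reaction -> pathway model of
  metabolism, attributing each hit reaction to one condition or both, and
  one-tailed Fisher pathway enrichment over reaction sets with
  Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ReactionMapping, Signature
from .diffexpr import adjust_pvalues
from .mmra import _fisher_one_sided

MIN_SET_SIZE = 3  # KS is degenerate below this


@dataclass
class ESResult:
    set_name: str
    direction: str | None  # "top" | "bottom" | None when skipped
    ks_statistic: float | None
    p_value: float | None
    adj_p: float | None = None
    skip_reason: str | None = None

    @property
    def skipped(self) -> bool:
        return self.skip_reason is not None


def rank_by_fc(de_records: pd.DataFrame, raw_p_filter: float = 0.05) -> list[str]:
    """Genes at raw p < filter, sorted by log2fc descending (ties by id)."""
    contrasts = de_records["contrast"].unique()
    if len(contrasts) > 1:
        raise ValueError("ranking must use a single contrast")
    kept = de_records[de_records["p_value"] < raw_p_filter]
    kept = kept.sort_values(["log2fc", "feature_id"], ascending=[False, True])
    return list(kept["feature_id"])


def ks_enrichment(
    ranked: list[str], gene_set: set[str], set_name: str = "", method: str = "auto"
) -> ESResult:
    """Two-sample KS test on rank positions of in-set vs out-of-set genes.

    ``direction`` is "top" when the in-set positions lead (the set piles up
    among the most up-regulated genes).  Sets with fewer than 3 members in
    the list, or covering the whole list, are skipped with a reason.
    ``method`` is passed to :func:`scipy.stats.ks_2samp` ("auto" switches to
    the exact null for small samples; "exact"/"asymp" force it).
    """
    positions_in = np.array([i for i, g in enumerate(ranked) if g in gene_set])
    if positions_in.size == 0:
        return ESResult(set_name, None, None, None, skip_reason="set disjoint from ranked list")
    if positions_in.size < MIN_SET_SIZE:
        return ESResult(set_name, None, None, None, skip_reason="fewer than 3 members in list")
    if positions_in.size == len(ranked):
        return ESResult(set_name, None, None, None, skip_reason="set covers the whole list")
    in_set = set(positions_in.tolist())
    positions_out = np.array([i for i in range(len(ranked)) if i not in in_set])
    res = stats.ks_2samp(positions_in, positions_out, method=method)
    # signed lead: positive when the in-set empirical CDF is above (earlier)
    grid = np.sort(np.concatenate([positions_in, positions_out]))
    cdf_in = np.searchsorted(np.sort(positions_in), grid, side="right") / positions_in.size
    cdf_out = np.searchsorted(np.sort(positions_out), grid, side="right") / positions_out.size
    direction = "top" if np.max(cdf_in - cdf_out) >= np.max(cdf_out - cdf_in) else "bottom"
    return ESResult(set_name, direction, float(res.statistic), float(res.pvalue))


def enrich_collection(
    ranked: list[str],
    collection: dict[str, set[str]],
    adjust: str = "BY",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """KS enrichment of every set, FDR-adjusted across the tested sets.

    Returns the full table (skipped sets carry their reason); the
    ``significant`` column flags adj_p < alpha.
    """
    results = [ks_enrichment(ranked, genes, name) for name, genes in sorted(collection.items())]
    tested = [r for r in results if not r.skipped]
    if tested:
        adj = adjust_pvalues([r.p_value for r in tested], adjust)
        for r, a in zip(tested, adj):
            r.adj_p = float(a)
    return pd.DataFrame(
        {
            "set_name": [r.set_name for r in results],
            "direction": [r.direction for r in results],
            "ks_statistic": [r.ks_statistic for r in results],
            "p_value": [r.p_value for r in results],
            "adj_p": [r.adj_p for r in results],
            "significant": [
                (r.adj_p is not None and r.adj_p < alpha) for r in results
            ],
            "skip_reason": [r.skip_reason for r in results],
        }
    )


def map_to_reactions(
    signatures: dict[str, Signature], mapping: ReactionMapping
) -> tuple[dict[str, int], set[str]]:
    """Attribute hit reactions to conditions: 1 = HFoleic only, 2 = HFepa
    only, 3 = both (versus the reference condition).

    ``signatures`` maps contrast names ("HFoleic_vs_reference",
    "HFepa_vs_reference") to signatures.  DE genes absent from the mapping
    are returned as the unmapped set.
    """
    hit: dict[str, set[str]] = {"HFoleic_vs_reference": set(), "HFepa_vs_reference": set()}
    unmapped: set[str] = set()
    for contrast, reactions in hit.items():
        sig = signatures.get(contrast)
        if sig is None:
            continue
        for gene in sig.genes:
            rxns = mapping.gene_to_reactions.get(gene)
            if rxns:
                reactions |= rxns
            else:
                unmapped.add(gene)
    oleic, epa = hit["HFoleic_vs_reference"], hit["HFepa_vs_reference"]
    attributes = {r: 1 for r in oleic - epa}
    attributes.update({r: 2 for r in epa - oleic})
    attributes.update({r: 3 for r in oleic & epa})
    return attributes, unmapped


def reaction_pathway_enrichment(
    attributed: dict[str, int],
    mapping: ReactionMapping,
    subset: int,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-tailed Fisher enrichment of one attribute class in each pathway.

    The universe is every reaction of the mapping; the query set is the
    reactions with attribute ``subset`` (1, 2 or 3); BH adjustment across
    pathways.  Pathways with zero reactions are skipped.
    """
    if subset not in (1, 2, 3):
        raise ValueError("subset must be 1, 2 or 3")
    universe = mapping.reactions
    query = {r for r, a in attributed.items() if a == subset} & universe
    pathways: dict[str, set[str]] = {}
    for rxn, pw in mapping.reaction_to_pathway.items():
        pathways.setdefault(pw, set()).add(rxn)
    rows = []
    for pw, rxns in sorted(pathways.items()):
        if not rxns:
            continue
        overlap = len(query & rxns)
        p = _fisher_one_sided(overlap, len(query), len(rxns), len(universe))
        rows.append({"pathway": pw, "n_reactions": len(rxns), "overlap": overlap, "p_value": p})
    table = pd.DataFrame(rows, columns=["pathway", "n_reactions", "overlap", "p_value"])
    if len(table):
        table["adj_p"] = adjust_pvalues(table["p_value"].to_numpy(), "BH")
        table["significant"] = table["adj_p"] < alpha
    else:
        table["adj_p"] = []
        table["significant"] = []
    return table
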