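"""Readers and writers for the pipeline's plain-text formats.

All tabular formats are TSV with UTF-8 encoding and dot decimals; gene
sets use GMT (set name, description, tab-separated members).  Parsers
fail with the offending line/column rather than silently coercing.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .containers import ExpressionStudy, PlantedTruth, ReactionMapping, Signature, TargetDatabaseSet
from .simulate import SimulationConfig


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Expression matrix: first column feature ids, header row sample ids."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"expression matrix not found: {path}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicated feature ids {dupes[:5]}")
    try:
        out = df.astype(float)
    except ValueError:
        for i, (feat, row) in enumerate(df.iterrows()):
            for col, val in row.items():
                try:
                    float(val)
                except (TypeError, ValueError):
                    raise ValueError(
                        f"{path}: non-numeric cell at row {i + 2} (feature {feat!r}), "
                        f"column {col!r}: {val!r}"
                    ) from None
        raise
    if out.isna().any().any():
        raise ValueError(f"{path}: matrix contains missing values")
    out.index.name = None
    return out


def write_expression_tsv(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="feature_id")


def read_annotation_tsv(path: str | Path) -> pd.Series:
    """Two-column TSV: sample_id, condition."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"annotation file not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] != 2:
        raise ValueError(f"{path}: expected 2 columns (sample_id, condition), got {df.shape[1]}")
    df.columns = ["sample_id", "condition"]
    if df["sample_id"].duplicated().any():
        raise ValueError(f"{path}: duplicated sample ids")
    return pd.Series(df["condition"].to_numpy(), index=df["sample_id"], name="condition")


def write_annotation_tsv(annotation: pd.Series, path: str | Path) -> None:
    pd.DataFrame({"sample_id": annotation.index, "condition": annotation.to_numpy()}).to_csv(
        path, sep="\t", index=False
    )


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    sets: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT lines need name, description, >=1 member")
            name = fields[0]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicated set name {name!r}")
            sets[name] = set(fields[2:])
    return sets


def write_gmt(sets: dict[str, set[str]], path: str | Path, description: str = "na") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in sorted(sets):
            members = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\t{description}\t{members}\n")


def signature_to_gmt(signature: Signature, path: str | Path) -> None:
    write_gmt(
        {
            f"{signature.contrast}_up": set(signature.up),
            f"{signature.contrast}_down": set(signature.down),
        },
        path,
        description=signature.contrast,
    )


def read_targets_tsv(path: str | Path) -> TargetDatabaseSet:
    """Three-column TSV: mirna_id, gene_id, source."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    expected = ["mirna_id", "gene_id", "source"]
    if list(df.columns) != expected:
        raise ValueError(f"{path}: expected columns {expected}, got {list(df.columns)}")
    sources: dict[str, dict[str, set[str]]] = {}
    for mirna, gene, source in df.itertuples(index=False):
        sources.setdefault(source, {}).setdefault(mirna, set()).add(gene)
    return TargetDatabaseSet(sources=sources)


def write_targets_tsv(dbset: TargetDatabaseSet, path: str | Path) -> None:
    rows = [
        {"mirna_id": m, "gene_id": g, "source": source}
        for source in sorted(dbset.sources)
        for m in sorted(dbset.sources[source])
        for g in sorted(dbset.sources[source][m])
    ]
    pd.DataFrame(rows, columns=["mirna_id", "gene_id", "source"]).to_csv(
        path, sep="\t", index=False
    )


def read_reaction_mapping_tsv(path: str | Path) -> ReactionMapping:
    """Three-column TSV: gene_id, reaction_id, pathway."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    expected = ["gene_id", "reaction_id", "pathway"]
    if list(df.columns) != expected:
        raise ValueError(f"{path}: expected columns {expected}, got {list(df.columns)}")
    gene_to_reactions: dict[str, set[str]] = {}
    reaction_to_pathway: dict[str, str] = {}
    for lineno, (gene, rxn, pw) in enumerate(df.itertuples(index=False), 2):
        gene_to_reactions.setdefault(gene, set()).add(rxn)
        if rxn in reaction_to_pathway and reaction_to_pathway[rxn] != pw:
            raise ValueError(f"{path}:{lineno}: reaction {rxn!r} mapped to two pathways")
        reaction_to_pathway[rxn] = pw
    return ReactionMapping(gene_to_reactions, reaction_to_pathway)


def write_reaction_mapping_tsv(mapping: ReactionMapping, path: str | Path) -> None:
    rows = [
        {"gene_id": g, "reaction_id": r, "pathway": mapping.reaction_to_pathway[r]}
        for g in sorted(mapping.gene_to_reactions)
        for r in sorted(mapping.gene_to_reactions[g])
    ]
    pd.DataFrame(rows, columns=["gene_id", "reaction_id", "pathway"]).to_csv(
        path, sep="\t", index=False
    )


def write_de_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_de_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    needed = {"feature_id", "contrast", "log2fc", "p_value", "adj_p", "direction"}
    if not needed <= set(df.columns):
        raise ValueError(f"{path}: missing DE columns {sorted(needed - set(df.columns))}")
    return df


def write_truth_json(truth: PlantedTruth, path: str | Path) -> None:
    payload = {
        "regulations": sorted(list(r) for r in truth.regulations),
        "de_genes": {
            k: {"up": sorted(v[0]), "down": sorted(v[1])} for k, v in truth.de_genes.items()
        },
        "de_mirnas": {
            k: {"up": sorted(v[0]), "down": sorted(v[1])} for k, v in truth.de_mirnas.items()
        },
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")


def read_truth_json(path: str | Path) -> PlantedTruth:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    return PlantedTruth(
        regulations={tuple(r) for r in payload["regulations"]},
        de_genes={
            k: (set(v["up"]), set(v["down"])) for k, v in payload["de_genes"].items()
        },
        de_mirnas={
            k: (set(v["up"]), set(v["down"])) for k, v in payload["de_mirnas"].items()
        },
    )


def write_simulation_config(config: SimulationConfig, path: str | Path) -> None:
    """YAML (or JSON, by extension) dump with bit-exact round-trip."""
    path = Path(path)
    data = config.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n", encoding="utf-8")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=True), encoding="utf-8")


def read_simulation_config(path: str | Path) -> SimulationConfig:
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return SimulationConfig.from_dict(data)


def study_to_dir(study: ExpressionStudy, outdir: str | Path) -> dict[str, Path]:
    """Write a study (matrices, annotation, optional truth) into a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genes": outdir / "genes.tsv",
        "mirnas": outdir / "mirnas.tsv",
        "annotation": outdir / "annotation.tsv",
    }
    write_expression_tsv(study.gene_matrix, paths["genes"])
    write_expression_tsv(study.mirna_matrix, paths["mirnas"])
    write_annotation_tsv(study.annotation, paths["annotation"])
    if study.truth is not None:
        paths["truth"] = outdir / "truth.json"
        write_truth_json(study.truth, paths["truth"])
    return paths


def study_from_dir(indir: str | Path) -> ExpressionStudy:
    indir = Path(indir)
    truth_path = indir / "truth.json"
    study = ExpressionStudy(
        gene_matrix=read_expression_tsv(indir / "genes.tsv"),
        mirna_matrix=read_expression_tsv(indir / "mirnas.tsv"),
        annotation=read_annotation_tsv(indir / "annotation.tsv"),
        truth=read_truth_json(truth_path) if truth_path.exists() else None,
    )
    study.validate()
    return study
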