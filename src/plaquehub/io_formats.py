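"""Readers and writers for the plain-text formats the pipeline consumes.

All inputs are UTF-8 TSV (no CSV sniffing) so that a written table reads
back bit-identically.  Missing values are hard errors: the expression
matrices this pipeline targets are complete, and silently imputing would
corrupt every rank-based statistic downstream.

Formats
-------
expression TSV   header row of sample ids, first column gene ids, log2 values
labels TSV       two columns: sample id, group ("unstable" or "stable")
GMT              per line: set name TAB description TAB gene TAB gene ...
edge TSV         three columns: gene_a, gene_b, confidence (STRING 0-1000)
drug-target TSV  two columns: drug id, target gene id (one pair per line)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError

CASE = "unstable"
CONTROL = "stable"
GROUPS = (CASE, CONTROL)


@dataclass
class ExpressionMatrix:
    """Genes x samples log2 expression with a two-group sample labelling."""

    data: pd.DataFrame  # index = gene ids, columns = sample ids
    groups: dict[str, str]  # sample id -> "unstable" | "stable"

    def __post_init__(self) -> None:
        idx = self.data.index
        cols = self.data.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise FormatError(f"duplicate gene identifier {dup!r}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise FormatError(f"duplicate sample identifier {dup!r}")
        missing = [s for s in cols if s not in self.groups]
        if missing:
            raise FormatError(f"samples missing a group label: {missing}")
        bad = {g for g in self.groups.values()} - set(GROUPS)
        if bad:
            raise FormatError(f"unknown group labels {sorted(bad)}; expected {GROUPS}")
        vals = self.data.to_numpy()
        if vals.size and not np.all(np.isfinite(vals.astype(float))):
            raise FormatError("expression values must all be finite")
        for grp in GROUPS:
            if not any(self.groups[s] == grp for s in cols):
                raise FormatError(f"group {grp!r} has no samples")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.data.columns if self.groups[s] == group]

    @property
    def case_samples(self) -> list[str]:
        return self.samples_in(CASE)

    @property
    def control_samples(self) -> list[str]:
        return self.samples_in(CONTROL)


@dataclass
class GeneSetCollection:
    """Named gene sets (signatures, annotation terms)."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise FormatError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                # internal constructor path: dedup preserving order
                seen: dict[str, None] = dict.fromkeys(genes)
                self.sets[name] = list(seen)

    def __len__(self) -> int:
        return len(self.sets)

    def items(self):
        return self.sets.items()


@dataclass
class EdgeTable:
    """Scored interaction records on the STRING 0-1000 confidence scale."""

    records: pd.DataFrame  # columns gene_a, gene_b, confidence

    def __post_init__(self) -> None:
        df = self.records
        expected = ["gene_a", "gene_b", "confidence"]
        if list(df.columns) != expected:
            raise FormatError(f"edge table columns must be {expected}")
        if len(df):
            conf = df["confidence"].to_numpy()
            if conf.min() < 0 or conf.max() > 1000:
                bad = df[(df.confidence < 0) | (df.confidence > 1000)].iloc[0]
                raise FormatError(
                    f"confidence {bad.confidence} for edge "
                    f"({bad.gene_a},{bad.gene_b}) outside [0,1000]"
                )
            if (df["gene_a"].str.len() == 0).any() or (df["gene_b"].str.len() == 0).any():
                raise FormatError("edge endpoints must be non-empty identifiers")

    def __len__(self) -> int:
        return len(self.records)


DrugTargetMap = dict[str, set[str]]


def _read_lines(path) -> list[str]:
    with open(path, encoding="utf-8") as fh:
        return fh.read().splitlines()


def read_expression(path, labels_path) -> ExpressionMatrix:
    """Parse a genes x samples TSV plus a sample->group label TSV."""
    lines = _read_lines(path)
    if not lines:
        raise FormatError(f"{path}: empty expression file")
    header = lines[0].split("\t")
    sample_ids = header[1:]
    genes: list[str] = []
    rows: list[list[float]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) != len(header):
            raise FormatError(
                f"{path}:{lineno}: expected {len(header)} fields, got {len(parts)}"
            )
        gene = parts[0]
        vals = []
        for sample, cell in zip(sample_ids, parts[1:]):
            try:
                v = float(cell)
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric cell {cell!r} "
                    f"(gene {gene!r}, sample {sample!r})"
                ) from None
            if not np.isfinite(v):
                raise FormatError(
                    f"{path}:{lineno}: non-finite cell {cell!r} "
                    f"(gene {gene!r}, sample {sample!r})"
                )
            vals.append(v)
        if gene in set(genes):
            raise FormatError(f"{path}:{lineno}: duplicate gene row {gene!r}")
        genes.append(gene)
        rows.append(vals)
    data = pd.DataFrame(rows, index=pd.Index(genes, name="gene"), columns=sample_ids)

    groups: dict[str, str] = {}
    for lineno, line in enumerate(_read_lines(labels_path), start=1):
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise FormatError(f"{labels_path}:{lineno}: expected 2 fields")
        sample, grp = parts
        if grp not in GROUPS:
            raise FormatError(
                f"{labels_path}:{lineno}: group {grp!r} not in {GROUPS}"
            )
        if sample in groups:
            raise FormatError(f"{labels_path}:{lineno}: duplicate sample {sample!r}")
        groups[sample] = grp
    missing = [s for s in sample_ids if s not in groups]
    if missing:
        raise FormatError(f"{labels_path}: no label for samples {missing}")
    return ExpressionMatrix(data, {s: groups[s] for s in sample_ids})


def write_expression(expr: ExpressionMatrix, path, labels_path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene\t" + "\t".join(expr.sample_ids) + "\n")
        for gene, row in expr.data.iterrows():
            fh.write(gene + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")
    with open(labels_path, "w", encoding="utf-8") as fh:
        for s in expr.sample_ids:
            fh.write(f"{s}\t{expr.groups[s]}\n")


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: one gene set per line, genes deduplicated in order."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    for lineno, line in enumerate(_read_lines(path), start=1):
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise FormatError(f"{path}:{lineno}: GMT line has {len(parts)} fields (<3)")
        name, desc, *genes = parts
        if name in sets:
            raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
        genes = [g for g in genes if g]
        if not genes:
            raise FormatError(f"{path}:{lineno}: set {name!r} has no genes")
        sets[name] = list(dict.fromkeys(genes))
        descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, genes in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def read_edge_list(path) -> EdgeTable:
    """Parse a three-column TSV of scored interactions."""
    recs: list[tuple[str, str, int]] = []
    lines = _read_lines(path)
    start = 0
    if lines and lines[0].split("\t")[:3] == ["gene_a", "gene_b", "confidence"]:
        start = 1  # optional header
    for lineno, line in enumerate(lines[start:], start=start + 1):
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise FormatError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
        a, b, conf_s = parts[0], parts[1], parts[2]
        if not a or not b:
            raise FormatError(f"{path}:{lineno}: empty gene identifier")
        try:
            conf = int(float(conf_s))
        except ValueError:
            raise FormatError(f"{path}:{lineno}: non-numeric confidence {conf_s!r}") from None
        if not 0 <= conf <= 1000:
            raise FormatError(f"{path}:{lineno}: confidence {conf} outside [0,1000]")
        recs.append((a, b, conf))
    df = pd.DataFrame(recs, columns=["gene_a", "gene_b", "confidence"])
    df["gene_a"] = df["gene_a"].astype(str)
    df["gene_b"] = df["gene_b"].astype(str)
    df["confidence"] = df["confidence"].astype(int)
    return EdgeTable(df)


def write_edge_list(table: EdgeTable, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_a\tgene_b\tconfidence\n")
        for rec in table.records.itertuples(index=False):
            fh.write(f"{rec.gene_a}\t{rec.gene_b}\t{rec.confidence}\n")


def read_drug_targets(path) -> DrugTargetMap:
    """Parse a two-column drug/target TSV into drug -> set of gene ids."""
    mapping: dict[str, set[str]] = {}
    lines = _read_lines(path)
    start = 1 if lines and lines[0].split("\t")[:2] == ["drug_id", "gene_id"] else 0
    for lineno, line in enumerate(lines[start:], start=start + 1):
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) < 2 or not parts[0] or not parts[1]:
            raise FormatError(f"{path}:{lineno}: expected non-empty drug and gene fields")
        mapping.setdefault(parts[0], set()).add(parts[1])
    return mapping


def write_drug_targets(mapping: DrugTargetMap, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("drug_id\tgene_id\n")
        for drug in sorted(mapping):
            for gene in sorted(mapping[drug]):
                fh.write(f"{drug}\t{gene}\n")


def read_gene_list(path) -> list[str]:
    """One identifier per line; blank lines ignored; order preserved."""
    out = []
    for line in _read_lines(path):
        g = line.strip()
        if g:
            out.append(g)
    return list(dict.fromkeys(out))


def write_gene_list(genes, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g in genes:
            fh.write(f"{g}\n")
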