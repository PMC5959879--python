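"""Data model and tabular I/O for the analysis pipeline.

The pipeline consumes gene x sample normalized expression tables (TCGA
level-3 RSEM dialect with ``SYMBOL|ENTREZ`` row keys, or plain TSV),
clinical survival tables, subtype centroid tables, GMT-like immune marker
signatures, ortholog maps, and writes GCT/CLS pairs for external gene-set
tools.

Conventions:

* Text is UTF-8; decimals use a point (no locale parsing).
* Missing expression cells are distinct from zero.  A zero is a valid
  measurement; missingness enters only via explicit ``NA`` tokens here, or
  downstream when zeros are log-transformed.
* Duplicate gene rows are retained at read time; collapsing duplicates is
  an explicit downstream operation (see :mod:`immunorank.mouse_patterns`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

SUBTYPES = ("Classical", "Basal", "Primitive", "Secretory")


class FormatError(ValueError):
    """A file violated the expected tabular format."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneId:
    """A gene identified by symbol and/or positive Entrez id."""

    symbol: str | None = None
    entrez: int | None = None

    def __post_init__(self) -> None:
        if self.symbol is None and self.entrez is None:
            raise ValueError("GeneId needs at least one of symbol/entrez")
        if self.entrez is not None and self.entrez <= 0:
            raise ValueError(f"Entrez id must be positive, got {self.entrez}")

    @property
    def key(self) -> str:
        """Stable string key: ``SYMBOL|ENTREZ`` join when both are present."""
        if self.symbol is not None and self.entrez is not None:
            return f"{self.symbol}|{self.entrez}"
        if self.symbol is not None:
            return self.symbol
        return str(self.entrez)

    @classmethod
    def from_key(cls, key: str) -> "GeneId":
        """Parse a ``SYMBOL|ENTREZ`` row key (TCGA level-3 convention)."""
        if "|" in key:
            sym, _, ent = key.partition("|")
            symbol = None if sym in ("", "?") else sym
            try:
                entrez = int(ent)
            except ValueError as exc:
                raise FormatError(f"bad Entrez id in row key {key!r}") from exc
            return cls(symbol=symbol, entrez=entrez)
        return cls(symbol=key)


@dataclass
class ExpressionMatrix:
    """Gene x sample grid of nonnegative normalized expression values.

    ``values`` is a float DataFrame whose index parallels ``genes`` (one row
    per GeneId, by position — duplicate identifiers are allowed) and whose
    columns are the unique sample identifiers.  Missing cells are NaN.
    """

    genes: list[GeneId]
    values: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.genes) != self.values.shape[0]:
            raise ValueError("gene list and value rows disagree")
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise FormatError(f"duplicate sample identifier {dup!r}")
        arr = self.values.to_numpy()
        if np.any(arr[np.isfinite(arr)] < 0):
            r, c = np.argwhere(np.isfinite(arr) & (arr < 0))[0]
            raise FormatError(
                f"negative expression value at gene row {r} "
                f"({self.genes[r].key}), sample {self.values.columns[c]!r}"
            )

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def gene_keys(self) -> list[str]:
        return [g.key for g in self.genes]

    def subset_genes(self, rows: Sequence[int]) -> "ExpressionMatrix":
        rows = list(rows)
        return ExpressionMatrix(
            genes=[self.genes[i] for i in rows],
            values=self.values.iloc[rows].copy(),
        )

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(
            genes=list(self.genes), values=self.values.loc[:, list(samples)].copy()
        )


@dataclass
class RawClinicalRecord:
    """Raw survival fields extracted from a clinical annotation row.

    Deliberately unvalidated: inconsistencies (negative follow-up, a dead
    patient with no death date) are resolved by the survival preprocessor,
    which must see the raw values.
    """

    sample: str
    days_to_death: int | None = None
    days_to_last_followup: int | None = None
    days_to_last_known_alive: int | None = None
    vital_status_label: str = ""
    stage: str | None = None


@dataclass
class ClinicalTable:
    """Cleaned per-sample survival data on the years scale."""

    data: pd.DataFrame  # index: sample; columns: survival_years, event, stage

    def __post_init__(self) -> None:
        if (self.data["survival_years"] < 0).any():
            raise ValueError("negative survival_years")
        if not self.data["event"].isin((0, 1)).all():
            raise ValueError("event must be 0/1")

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    def aligned(self, samples: Sequence[str]) -> "ClinicalTable":
        return ClinicalTable(self.data.loc[list(samples)].copy())


@dataclass
class SubtypeCentroids:
    """Per-gene centroid profiles of the four squamous expression subtypes."""

    table: pd.DataFrame  # index: gene key; columns: the four subtypes
    genes: list[GeneId] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = set(SUBTYPES) - set(self.table.columns)
        if missing:
            raise ValueError(f"centroid table lacks subtypes: {sorted(missing)}")
        if self.table.index.duplicated().any():
            raise ValueError("duplicate gene in centroid table")
        if not self.genes:
            self.genes = [GeneId.from_key(k) for k in self.table.index]


@dataclass
class ImmuneSignature:
    """Immune cell-type marker lists.

    Each gene belongs to one or two cell types and carries an innate/adaptive
    immunity tag.  ``entries`` maps the gene key to ``(immunity, types)``.
    """

    entries: dict[str, tuple[str, tuple[str, ...]]]
    cell_types: list[str]

    def __post_init__(self) -> None:
        known = set(self.cell_types)
        for key, (_imm, types) in self.entries.items():
            if not 1 <= len(types) <= 2:
                raise ValueError(
                    f"gene {key!r} maps to {len(types)} cell types (allowed: 1-2)"
                )
            unknown = set(types) - known
            if unknown:
                raise ValueError(f"gene {key!r} references unknown cell types {unknown}")

    def genes_of(self, cell_type: str) -> list[str]:
        return [k for k, (_i, t) in self.entries.items() if cell_type in t]

    @property
    def n_genes(self) -> int:
        return len(self.entries)

    @property
    def n_single(self) -> int:
        return sum(1 for _i, t in self.entries.values() if len(t) == 1)

    @property
    def n_dual(self) -> int:
        return sum(1 for _i, t in self.entries.values() if len(t) == 2)


@dataclass
class OrthologMap:
    """Mouse-to-human ortholog pairs (no duplicates)."""

    pairs: list[tuple[GeneId, GeneId]]

    def __post_init__(self) -> None:
        seen = set()
        for m, h in self.pairs:
            k = (m.key, h.key)
            if k in seen:
                raise ValueError(f"duplicated ortholog pair {k}")
            seen.add(k)

    def human_of(self, mouse_symbol: str) -> list[GeneId]:
        return [h for m, h in self.pairs if m.symbol == mouse_symbol]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_NA_TOKENS = {"", "NA", "NaN", "nan", "null", "NULL", "[Not Available]"}


def read_expression_table(path: str | Path, dialect: str = "tcga_level3") -> ExpressionMatrix:
    """Read a gene x sample TSV of normalized expression.

    In the ``tcga_level3`` dialect row keys are ``SYMBOL|ENTREZ`` and are
    split into dual identifiers; ``plain`` keeps the key as a symbol.
    NA tokens become missing cells; negative values are a format error.
    """
    if dialect not in ("tcga_level3", "plain"):
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    seen: set[str] = set()
    for col in header:  # checked on the raw header: pandas mangles duplicates
        if col in seen:
            raise FormatError(f"duplicate sample id {col!r} in {path}")
        seen.add(col)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)

    def _parse(s: str) -> float:  # exact round-trip parsing
        if s in _NA_TOKENS:
            return np.nan
        try:
            return float(s)
        except ValueError as exc:
            raise FormatError(f"unparseable value {s!r} in {path}") from exc

    vals = df.map(_parse)
    arr = vals.to_numpy(dtype=float)
    neg = np.argwhere(np.isfinite(arr) & (arr < 0))
    if neg.size:
        r, c = neg[0]
        raise FormatError(
            f"negative value at row {df.index[r]!r}, column {df.columns[c]!r} in {path}"
        )
    if dialect == "tcga_level3":
        genes = [GeneId.from_key(k) for k in df.index]
    else:
        genes = [GeneId(symbol=k) for k in df.index]
    return ExpressionMatrix(genes=genes, values=vals.astype(float))


def write_expression_table(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write an ExpressionMatrix as TSV (row keys re-joined; NA for missing).

    Rendering uses pandas' shortest-roundtrip float formatting, so a
    read-write-read cycle is value-identical.
    """
    out = matrix.values.copy()
    out.index = pd.Index(matrix.gene_keys(), name="gene")
    out.to_csv(path, sep="\t", na_rep="NA", float_format=lambda v: repr(float(v)))


_CLINICAL_COLUMN_MAP = {
    "days_to_death": "days_to_death",
    "days_to_last_followup": "days_to_last_followup",
    "days_to_last_known_alive": "days_to_last_known_alive",
    "vital_status": "vital_status",
    "stage": "stage",
    "sample": "sample",
}


def read_clinical_table(
    path: str | Path, column_map: Mapping[str, str] | None = None
) -> list[RawClinicalRecord]:
    """Read raw clinical survival records from a TSV.

    ``column_map`` maps the canonical field names (keys of the default map)
    to the actual column headers, since clinical dialects vary.  Unparseable
    day values raise a record-level warning and the field is left absent.
    Values (including negative day counts) are passed through untouched:
    filtering belongs to the survival preprocessor.
    """
    cmap = dict(_CLINICAL_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)

    def _day(row: pd.Series, col: str, sample: str) -> int | None:
        name = cmap[col]
        if name not in row or row[name] in _NA_TOKENS:
            return None
        try:
            return int(float(row[name]))
        except ValueError:
            warnings.warn(f"sample {sample!r}: unparseable {col} value {row[name]!r}")
            return None

    records = []
    for _, row in df.iterrows():
        sample = row[cmap["sample"]]
        stage = row.get(cmap["stage"])
        records.append(
            RawClinicalRecord(
                sample=sample,
                days_to_death=_day(row, "days_to_death", sample),
                days_to_last_followup=_day(row, "days_to_last_followup", sample),
                days_to_last_known_alive=_day(row, "days_to_last_known_alive", sample),
                vital_status_label=row.get(cmap["vital_status"], "").strip().lower(),
                stage=None if stage in _NA_TOKENS or stage is None else stage,
            )
        )
    return records


def read_centroid_table(path: str | Path) -> SubtypeCentroids:
    """Read a centroid TSV: gene key column then one column per subtype."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return SubtypeCentroids(table=df.astype(float))


def read_signature_file(path: str | Path) -> ImmuneSignature:
    """Read a GMT-like immune signature.

    One line per cell type: label, innate/adaptive tag, then tab-separated
    gene tokens (``SYMBOL|ENTREZ`` or bare symbol).  A gene listed under
    three or more cell types violates the 1-2 rule and is an error.
    """
    cell_types: list[str] = []
    per_gene: dict[str, tuple[str, list[str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"signature line needs label, tag, genes: {line!r}")
            label, immunity = fields[0], fields[1]
            cell_types.append(label)
            for token in fields[2:]:
                if not token:
                    continue
                key = GeneId.from_key(token).key
                imm, types = per_gene.setdefault(key, (immunity, []))
                if label not in types:
                    types.append(label)
                if len(types) > 2:
                    raise FormatError(
                        f"gene {key!r} listed under {len(types)} cell types "
                        f"({types}); at most 2 allowed"
                    )
    entries = {k: (imm, tuple(t)) for k, (imm, t) in per_gene.items()}
    return ImmuneSignature(entries=entries, cell_types=cell_types)


def write_signature_file(sig: ImmuneSignature, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for ct in sig.cell_types:
            genes = sig.genes_of(ct)
            imm = next(
                (i for i, t in sig.entries.values() if ct in t), "innate"
            )
            fh.write("\t".join([ct, imm, *genes]) + "\n")


def read_ortholog_map(path: str | Path) -> OrthologMap:
    """Read a two-column TSV of (mouse gene, human gene) tokens."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    pairs = [
        (GeneId.from_key(m), GeneId.from_key(h))
        for m, h in zip(df.iloc[:, 0], df.iloc[:, 1])
    ]
    return OrthologMap(pairs=pairs)


def export_gene_set_inputs(
    matrix: ExpressionMatrix,
    classes: Mapping[str, int] | pd.Series,
    gct_path: str | Path,
    cls_path: str | Path,
    class_names: tuple[str, str] = ("CB", "PS"),
) -> None:
    """Write a GCT v1.2 expression file and a two-class CLS file.

    ``classes`` assigns 0/1 to every sample of the matrix (0 = first class
    name).  Class counts and sample order are preserved.  The pair is
    consumable by external gene-set enrichment tools.
    """
    classes = pd.Series(dict(classes) if not isinstance(classes, pd.Series) else classes)
    missing = [s for s in matrix.samples if s not in classes.index]
    if missing:
        raise ValueError(f"class missing for samples: {missing[:5]}")
    labels = classes.loc[matrix.samples].astype(int)
    if not labels.isin((0, 1)).all():
        raise ValueError("classes must be binary 0/1")

    with open(gct_path, "w", encoding="utf-8") as fh:
        fh.write("#1.2\n")
        fh.write(f"{matrix.n_genes}\t{matrix.n_samples}\n")
        fh.write("NAME\tDescription\t" + "\t".join(matrix.samples) + "\n")
        for gid, (_, row) in zip(matrix.genes, matrix.values.iterrows()):
            sym = gid.symbol if gid.symbol is not None else gid.key
            vals = "\t".join("NA" if pd.isna(v) else repr(float(v)) for v in row)
            fh.write(f"{sym}\t{gid.key}\t{vals}\n")

    with open(cls_path, "w", encoding="utf-8") as fh:
        fh.write(f"{matrix.n_samples} 2 1\n")
        fh.write(f"# {class_names[0]} {class_names[1]}\n")
        fh.write(" ".join(str(v) for v in labels) + "\n")


def read_gct(path: str | Path) -> ExpressionMatrix:
    """Read back a GCT v1.2 file written by :func:`export_gene_set_inputs`."""
    with open(path, encoding="utf-8") as fh:
        version = fh.readline().strip()
        if version != "#1.2":
            raise FormatError(f"unsupported GCT version line {version!r}")
        fh.readline()  # dimensions; trusted from the body
        df = pd.read_csv(fh, sep="\t", dtype=str, keep_default_na=False)
    genes = [GeneId.from_key(k) for k in df["Description"]]
    vals = df.drop(columns=["NAME", "Description"]).apply(
        lambda col: pd.to_numeric(col.map(lambda s: np.nan if s in _NA_TOKENS else s))
    )
    return ExpressionMatrix(genes=genes, values=vals.astype(float))
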