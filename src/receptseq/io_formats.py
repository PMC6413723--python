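"""Readers and writers for every external format the pipeline touches.

All downstream modules consume only the domain types defined here:
:class:`ExpressionMatrix`, :class:`PromoterSet`, :class:`PWM`,
:class:`InteractionNetwork` and :class:`GeneSetAnnotation`.  Tables are
tab-separated with a header row; comma-separated input is rejected rather
than guessed.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "ExpressionMatrix",
    "PromoterSet",
    "PWM",
    "InteractionNetwork",
    "GeneSetAnnotation",
    "read_fasta",
    "write_fasta",
    "read_pwm_library",
    "write_pwm_library",
    "read_gmt",
    "write_gmt",
    "read_table",
    "write_table",
]

_BASES = ("A", "C", "G", "T")
_FASTA_ALPHABET = set("ACGTN")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Gene-level abundance matrix (genes x samples) with condition labels.

    Values are FPKM-like non-negative abundances.  Exactly two distinct
    condition labels are required (e.g. ``day3``/``day4``), each with at
    least two replicate samples.
    """

    values: pd.DataFrame                  # index = gene ids, columns = sample ids
    condition_of_sample: pd.Series        # index = sample ids -> label

    def __post_init__(self) -> None:
        v = self.values
        if v.index.duplicated().any():
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups}")
        if v.columns.duplicated().any():
            dups = v.columns[v.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        missing = set(v.columns) - set(self.condition_of_sample.index)
        if missing:
            raise ValueError(f"samples without a condition label: {sorted(missing)}")
        self.condition_of_sample = self.condition_of_sample.reindex(v.columns)
        labels = self.condition_of_sample.unique()
        if len(labels) != 2:
            raise ValueError(f"expected exactly two condition labels, got {list(labels)}")
        for lab in labels:
            n = int((self.condition_of_sample == lab).sum())
            if n < 2:
                raise ValueError(f"condition {lab!r} has {n} sample(s); need >= 2")
        v.index.name = "gene_id"
        arr = v.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValueError("expression values must be finite")
        if (arr < 0).any():
            raise ValueError("expression values must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def conditions(self) -> list[str]:
        """The two condition labels, in order of first appearance."""
        return list(dict.fromkeys(self.condition_of_sample))

    def samples_of(self, condition: str) -> list[str]:
        mask = self.condition_of_sample == condition
        return list(self.condition_of_sample.index[mask])


@dataclass
class PromoterSet:
    """Promoter sequences keyed by gene id; nominally 1 kb upstream of TSS."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        for gid, seq in self.sequences.items():
            if not seq:
                raise ValueError(f"empty sequence for gene {gid!r}")
            bad = set(seq) - _FASTA_ALPHABET
            if bad:
                raise ValueError(f"invalid characters {sorted(bad)} in sequence of {gid!r}")

    def __len__(self) -> int:
        return len(self.sequences)

    def __getitem__(self, gene_id: str) -> str:
        return self.sequences[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.sequences

    @property
    def gene_ids(self) -> list[str]:
        return list(self.sequences)


@dataclass
class PWM:
    """Position count/frequency matrix for a transcription-factor motif.

    ``matrix`` is 4 x L, rows in fixed order A, C, G, T.
    """

    tf_name: str
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != 4:
            raise ValueError(f"PWM {self.tf_name!r}: matrix must be 4 x L, got {m.shape}")
        if m.shape[1] < 4:
            raise ValueError(f"PWM {self.tf_name!r}: motif length must be >= 4, got {m.shape[1]}")
        if (m < 0).any():
            raise ValueError(f"PWM {self.tf_name!r}: negative counts")
        if (m.sum(axis=0) == 0).any():
            raise ValueError(f"PWM {self.tf_name!r}: all-zero column")
        self.matrix = m

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def frequencies(self) -> np.ndarray:
        """Column-normalized matrix; each column sums to 1."""
        return self.matrix / self.matrix.sum(axis=0, keepdims=True)

    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.matrix.argmax(axis=0))


@dataclass
class InteractionNetwork:
    """Undirected gene-gene interaction edges with combined scores in [0, 1]."""

    edges: pd.DataFrame  # columns: node_a, node_b, combined_score

    def __post_init__(self) -> None:
        e = self.edges
        required = ["node_a", "node_b", "combined_score"]
        missing = [c for c in required if c not in e.columns]
        if missing:
            raise ValueError(f"edge table missing columns: {missing}")
        scores = e["combined_score"].to_numpy(dtype=float)
        if not np.isfinite(scores).all():
            raise ValueError("edge scores must be finite")
        if ((scores < 0) | (scores > 1)).any():
            raise ValueError("edge scores must lie in [0, 1]")
        if (e["node_a"] == e["node_b"]).any():
            loops = e.loc[e["node_a"] == e["node_b"], "node_a"].tolist()
            raise ValueError(f"self-loops not allowed: {loops}")
        key = e.apply(lambda r: tuple(sorted((r["node_a"], r["node_b"]))), axis=1)
        if key.duplicated().any():
            dups = key[key.duplicated()].tolist()
            raise ValueError(f"duplicate undirected edges: {dups}")

    @property
    def nodes(self) -> list[str]:
        seen: dict[str, None] = {}
        for a, b in zip(self.edges["node_a"], self.edges["node_b"]):
            seen.setdefault(a)
            seen.setdefault(b)
        return list(seen)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


@dataclass
class GeneSetAnnotation:
    """GO-style term -> member-gene annotation over a declared background."""

    terms: dict[str, tuple[str, list[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term_id, (_, members) in self.terms.items():
            if not members:
                raise ValueError(f"term {term_id!r} has no members")

    def __len__(self) -> int:
        return len(self.terms)

    def members(self, term_id: str) -> list[str]:
        return self.terms[term_id][1]

    def name(self, term_id: str) -> str:
        return self.terms[term_id][0]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> PromoterSet:
    """Read promoter sequences from FASTA.

    The header token before the first whitespace is the gene id; sequences
    are uppercased.  Duplicate ids, characters outside ``{A,C,G,T,N}``
    (either case) and empty files are errors.
    """
    sequences: dict[str, str] = {}
    n = 0
    for record in SeqIO.parse(str(path), "fasta"):
        n += 1
        gid = record.id
        if gid in sequences:
            raise ValueError(f"duplicate gene id in FASTA: {gid!r}")
        seq = str(record.seq).upper()
        bad = set(seq) - _FASTA_ALPHABET
        if bad:
            raise ValueError(
                f"record {gid!r}: characters outside A/C/G/T/N: {sorted(bad)}"
            )
        sequences[gid] = seq
    if n == 0:
        raise ValueError(f"no FASTA records found in {path}")
    return PromoterSet(sequences)


def write_fasta(promoters: PromoterSet, path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for gid, seq in promoters.sequences.items():
            fh.write(f">{gid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# TRANSFAC-style PWM blocks
# ---------------------------------------------------------------------------

def read_pwm_library(path) -> list[PWM]:
    """Parse a TRANSFAC-style matrix file into a list of :class:`PWM`.

    Each block carries an ``ID`` (or ``NA``) line naming the factor, a
    ``P0`` header line giving the base column order, numbered position rows
    with four counts, and a ``//`` terminator.  The base order on the header
    line is honored and remapped to the fixed A,C,G,T row order.
    """
    with open(path) as fh:
        text = fh.read()
    blocks = [b for b in text.split("//") if b.strip()]
    pwms: list[PWM] = []
    for block in blocks:
        name = None
        order: list[int] | None = None
        rows: list[list[float]] = []
        for line in block.splitlines():
            line = line.strip()
            if not line:
                continue
            tag, _, rest = line.partition(" ")
            tag = tag.strip()
            rest = rest.strip()
            if tag in ("ID", "NA") and name is None:
                name = rest
            elif tag in ("P0", "PO"):
                bases = rest.split()
                if sorted(bases) != sorted(_BASES):
                    raise ValueError(f"block {name!r}: P0 line must list A C G T, got {bases}")
                order = [bases.index(b) for b in _BASES]
            elif tag[:1].isdigit():
                fields = rest.split()
                # a trailing consensus letter is allowed and dropped
                if len(fields) == 5 and fields[4].isalpha():
                    fields = fields[:4]
                if len(fields) != 4:
                    raise ValueError(
                        f"block {name!r}: position row {tag} has {len(fields)} counts, expected 4"
                    )
                try:
                    rows.append([float(x) for x in fields])
                except ValueError as exc:
                    raise ValueError(f"block {name!r}: non-numeric count in row {tag}") from exc
        if name is None:
            raise ValueError("matrix block without ID/NA line")
        if not rows:
            raise ValueError(f"block {name!r}: no position rows")
        mat = np.array(rows, dtype=float).T  # base x position, in file order
        if order is not None:
            mat = mat[order]  # order[i] = file column holding base A,C,G,T[i]
        if (mat < 0).any():
            raise ValueError(f"block {name!r}: negative counts")
        pwms.append(PWM(tf_name=name, matrix=mat))
    if not pwms:
        raise ValueError(f"no PWM blocks found in {path}")
    return pwms


def write_pwm_library(pwms: list[PWM], path) -> None:
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f"ID {pwm.tf_name}\n")
            fh.write("P0 A C G T\n")
            for i in range(pwm.length):
                col = pwm.matrix[:, i]
                fields = " ".join(_fmt_num(x) for x in col)
                fh.write(f"{i + 1:02d} {fields}\n")
            fh.write("//\n")


def _fmt_num(x: float) -> str:
    return repr(int(x)) if float(x).is_integer() else repr(float(x))


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------

def read_gmt(path) -> GeneSetAnnotation:
    """Read gene-set annotations in GMT (term, description, members...)."""
    terms: dict[str, tuple[str, list[str]]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"line {ln}: GMT requires term, description and >=1 member")
            term_id, desc, members = fields[0], fields[1], [g for g in fields[2:] if g]
            if term_id in terms:
                raise ValueError(f"duplicate term id {term_id!r}")
            terms[term_id] = (desc, members)
    if not terms:
        raise ValueError(f"no terms found in {path}")
    return GeneSetAnnotation(terms)


def write_gmt(annotation: GeneSetAnnotation, path) -> None:
    with open(path, "w") as fh:
        for term_id, (desc, members) in annotation.terms.items():
            fh.write("\t".join([term_id, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

TABLE_SCHEMAS = {
    "expression": None,  # special layout, see below
    "edges": ["node_a", "node_b", "combined_score"],
    "ranked_profile": ["drug_id", "rank", "gene_id"],
    "de_table": ["gene_id", "log2fc", "p_value"],
    "ortholog_map": ["mouse_gene", "human_gene"],
    "ct_values": ["sample_id", "condition", "gene_id", "ct"],
}

_NUMERIC_COLUMNS = {
    "edges": ["combined_score"],
    "ranked_profile": ["rank"],
    "de_table": ["log2fc", "p_value"],
    "ortholog_map": [],
    "ct_values": ["ct"],
}


def read_table(path, schema: str, score_scale: str = "unit"):
    """Read a typed TSV table.

    ``schema`` selects the layout: ``expression`` (gene_id + sample columns
    with a second header row mapping sample -> condition), ``edges``,
    ``ranked_profile``, ``de_table``, ``ortholog_map`` or ``ct_values``.
    ``score_scale`` applies to edges only: ``"string999"`` divides raw
    STRING-export combined scores by 999 onto the unit scale.
    """
    if schema not in TABLE_SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}; one of {sorted(TABLE_SCHEMAS)}")
    if schema == "expression":
        return _read_expression(path)

    with open(path) as fh:
        header = fh.readline()
    if "\t" not in header and "," in header:
        raise ValueError("comma-separated input detected; tables must be tab-separated")
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = TABLE_SCHEMAS[schema]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{schema} table missing required column(s): {missing}")
    df = df[required].copy()
    for col in _NUMERIC_COLUMNS[schema]:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based incl. header
            raise ValueError(f"non-numeric value in column {col!r} at line {row}")
        if converted.isna().any():
            row = int(np.flatnonzero(converted.isna().to_numpy())[0]) + 2
            raise ValueError(f"missing value in numeric column {col!r} at line {row}")
        if not np.isfinite(converted.to_numpy(dtype=float)).all():
            raise ValueError(f"non-finite value in numeric column {col!r}")
        df[col] = converted.astype(float)

    if schema == "edges":
        if score_scale == "string999":
            df["combined_score"] = df["combined_score"] / 999.0
        elif score_scale != "unit":
            raise ValueError(f"score_scale must be 'unit' or 'string999', got {score_scale!r}")
        return InteractionNetwork(df.reset_index(drop=True))
    if schema == "ranked_profile":
        df["rank"] = df["rank"].astype(int)
        for drug, grp in df.groupby("drug_id", sort=False):
            if grp["gene_id"].duplicated().any():
                dup = grp.loc[grp["gene_id"].duplicated(), "gene_id"].iloc[0]
                raise ValueError(f"profile {drug!r}: duplicated gene {dup!r}")
            ranks = np.sort(grp["rank"].to_numpy())
            if not np.array_equal(ranks, np.arange(1, len(grp) + 1)):
                raise ValueError(f"profile {drug!r}: ranks must be 1..n without gaps")
        return df.reset_index(drop=True)
    if schema == "de_table":
        if df["gene_id"].duplicated().any():
            dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise ValueError(f"duplicated gene {dup!r} in DE table")
    if schema == "ortholog_map":
        df = df.map(lambda s: s.strip() if isinstance(s, str) else s)
    return df.reset_index(drop=True)


def _read_expression(path) -> ExpressionMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        cond_line = fh.readline().rstrip("\n")
        body = fh.read()
    if "\t" not in header and "," in header:
        raise ValueError("comma-separated input detected; tables must be tab-separated")
    cols = header.split("\t")
    if not cols or cols[0] != "gene_id":
        raise ValueError("expression table must start with a 'gene_id' column")
    cond_fields = cond_line.split("\t")
    if not cond_fields or cond_fields[0] != "condition":
        raise ValueError("second header row must start with 'condition'")
    samples = cols[1:]
    if len(cond_fields) - 1 != len(samples):
        raise ValueError("condition row length does not match sample columns")
    conditions = pd.Series(cond_fields[1:], index=samples, name="condition")
    df = pd.read_csv(io.StringIO(header + "\n" + body), sep="\t", index_col="gene_id")
    for col in samples:
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise ValueError(f"non-numeric value in sample column {col!r}")
    return ExpressionMatrix(values=df.astype(float), condition_of_sample=conditions)


def write_table(obj, path, schema: str) -> None:
    """Write a domain object back to its TSV layout (inverse of read_table)."""
    if schema == "expression":
        em: ExpressionMatrix = obj
        with open(path, "w") as fh:
            fh.write("gene_id\t" + "\t".join(em.sample_ids) + "\n")
            fh.write("condition\t" + "\t".join(em.condition_of_sample) + "\n")
            for gid, row in em.values.iterrows():
                fh.write(gid + "\t" + "\t".join(repr(float(x)) for x in row) + "\n")
        return
    if schema == "edges":
        df = obj.edges if isinstance(obj, InteractionNetwork) else obj
    else:
        df = obj
    df = df[TABLE_SCHEMAS[schema]]
    df.to_csv(path, sep="\t", index=False)
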