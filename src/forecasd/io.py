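"""Readers and writers for the external text formats the tool consumes.

All tabular dialects are plain UTF-8 text with LF line endings and ``NA`` as
the missing-value token.  Gene identifiers are opaque, case-sensitive strings;
harmonization across sources is exact-match only (alias resolution is a
non-goal).

Formats
-------
* expression bundle: matrix CSV + row-metadata CSV + column-metadata CSV
  (the BrainSpan download dialect);
* interaction edge list: whitespace/tab-delimited ``geneA geneB score`` rows
  (STRING dialect; extra columns ignored, optional header tolerated);
* gene tables (scores, priors, pLI), DNM tables and eQTL/GWAS tables:
  TSV with a header row.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    DimensionMismatchError,
    DuplicateGeneError,
    FormatError,
    MissingColumnError,
    ValidationError,
)

logger = logging.getLogger(__name__)

NA_TOKEN = "NA"
#: significant digits preserved by every writer (round-trip contract)
FLOAT_FORMAT = "%.12g"

# Age conversion constants.  The developmental atlas labels ages as
# "<n> pcw|mos|yrs"; everything is mapped onto a single post-conception-week
# scale with birth at 40 pcw, 1 month = 52/12 weeks and 1 year = 52 weeks.
# Any strictly monotone convention would do; this one is fixed and documented.
BIRTH_PCW = 40.0
WEEKS_PER_MONTH = 52.0 / 12.0
WEEKS_PER_YEAR = 52.0

_AGE_RE = re.compile(r"^\s*(\d+(?:\.\d+)?)\s*(pcw|mos|yrs)\s*$", re.IGNORECASE)

CONSEQUENCE_CLASSES = ("LOF", "missense", "synonymous")


def parse_age(label: str) -> float:
    """Convert an age label such as ``"8 pcw"`` or ``"4 mos"`` to numeric
    post-conception weeks.

    Postnatal units are converted with fixed constants (birth = 40 pcw,
    1 mos = 52/12 weeks, 1 yrs = 52 weeks), which makes the mapping strictly
    monotone in chronological age.

    Raises
    ------
    FormatError
        If the label does not match ``<number> pcw|mos|yrs``.
    """
    if not isinstance(label, str):
        raise FormatError(f"age label must be a string, got {label!r}")
    m = _AGE_RE.match(label)
    if m is None:
        raise FormatError(f"unparseable age label: {label!r}")
    value = float(m.group(1))
    unit = m.group(2).lower()
    if unit == "pcw":
        age = value
    elif unit == "mos":
        age = BIRTH_PCW + value * WEEKS_PER_MONTH
    else:  # yrs
        age = BIRTH_PCW + value * WEEKS_PER_YEAR
    if not np.isfinite(age) or age <= 0:
        raise FormatError(f"age label {label!r} maps to non-positive age {age}")
    return age


# ---------------------------------------------------------------------------
# Expression bundle
# ---------------------------------------------------------------------------


@dataclass
class ExpressionBundle:
    """A gene x sample expression matrix plus per-sample metadata.

    ``values`` is a DataFrame indexed by gene with one column per sample;
    ``sample_meta`` is indexed by sample with columns ``donor``, ``region``
    and ``age_pcw`` (numeric post-conception weeks).
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def regions(self) -> list[str]:
        return sorted(self.sample_meta["region"].unique())

    def validate(self) -> None:
        if not self.genes.is_unique:
            dup = self.genes[self.genes.duplicated()][0]
            raise DuplicateGeneError(f"duplicate gene identifier: {dup!r}")
        for col in ("donor", "region", "age_pcw"):
            if col not in self.sample_meta.columns:
                raise MissingColumnError(f"sample metadata lacks column {col!r}")
        if not self.samples.equals(self.sample_meta.index):
            raise DimensionMismatchError(
                f"matrix has {len(self.samples)} samples but metadata describes "
                f"{len(self.sample_meta)}"
            )
        ages = self.sample_meta["age_pcw"].to_numpy(float)
        if not np.all(np.isfinite(ages)) or np.any(ages <= 0):
            raise ValidationError("every sample needs a finite age_pcw > 0")
        vals = self.values.to_numpy(float)
        if not np.all(np.isfinite(vals)):
            raise ValidationError("expression values must be finite")
        if np.any(vals < 0):
            raise ValidationError("expression values must be non-negative")

    def subset_samples(self, samples: pd.Index | list[str]) -> "ExpressionBundle":
        return ExpressionBundle(
            values=self.values.loc[:, samples],
            sample_meta=self.sample_meta.loc[samples],
        )


def _find_column(df: pd.DataFrame, candidates: tuple[str, ...], what: str) -> str:
    for name in candidates:
        if name in df.columns:
            return name
    raise MissingColumnError(
        f"metadata lacks a {what} column (looked for {', '.join(candidates)})"
    )


def read_expression_bundle(matrix_file, row_meta, col_meta) -> ExpressionBundle:
    """Read an expression bundle in the matrix + rows/columns metadata dialect.

    The matrix CSV holds numbers only; a leading integer row-number column
    (as shipped in the atlas download) is detected and dropped.  Row metadata
    must provide a gene identifier column; column metadata must provide donor,
    region ("structure") and an age label parseable by :func:`parse_age`
    (plain numeric labels are taken as pcw directly).
    """
    mat = pd.read_csv(matrix_file, header=None)
    rows = pd.read_csv(row_meta)
    cols = pd.read_csv(col_meta)

    # Drop a leading row-number column if present.
    if mat.shape[1] == len(cols) + 1:
        first = mat.iloc[:, 0].to_numpy()
        if np.array_equal(first, np.arange(1, len(mat) + 1)) or np.array_equal(
            first, np.arange(len(mat))
        ):
            mat = mat.iloc[:, 1:]

    gene_col = _find_column(rows, ("gene", "gene_symbol", "ensembl_gene_id"), "gene")
    donor_col = _find_column(cols, ("donor", "donor_id", "donor_name"), "donor")
    region_col = _find_column(
        cols, ("region", "structure", "structure_acronym", "structure_name"), "region"
    )
    age_col = _find_column(cols, ("age", "age_label", "age_pcw"), "age")

    if mat.shape[0] != len(rows):
        raise DimensionMismatchError(
            f"matrix has {mat.shape[0]} rows but row metadata describes {len(rows)}"
        )
    if mat.shape[1] != len(cols):
        raise DimensionMismatchError(
            f"matrix has {mat.shape[1]} columns but column metadata describes {len(cols)}"
        )

    genes = rows[gene_col].astype(str)
    if genes.duplicated().any():
        dup = genes[genes.duplicated()].iloc[0]
        raise DuplicateGeneError(f"duplicate gene id in row metadata: {dup!r}")

    if "sample" in cols.columns:
        sample_ids = cols["sample"].astype(str).tolist()
    else:
        sample_ids = [f"S{i + 1:04d}" for i in range(len(cols))]

    def _age(label) -> float:
        if isinstance(label, (int, float, np.integer, np.floating)):
            return float(label)
        try:
            return float(label)
        except (TypeError, ValueError):
            return parse_age(str(label))

    meta = pd.DataFrame(
        {
            "donor": cols[donor_col].astype(str).to_numpy(),
            "region": cols[region_col].astype(str).to_numpy(),
            "age_pcw": [_age(a) for a in cols[age_col]],
        },
        index=pd.Index(sample_ids, name="sample"),
    )
    values = pd.DataFrame(
        mat.to_numpy(float), index=pd.Index(genes, name="gene"), columns=meta.index
    )
    return ExpressionBundle(values=values, sample_meta=meta)


def write_expression_bundle(bundle: ExpressionBundle, matrix_file, row_meta, col_meta) -> None:
    """Write a bundle back out in the same three-file dialect."""
    bundle.values.to_csv(matrix_file, header=False, index=False, float_format=FLOAT_FORMAT)
    pd.DataFrame({"gene": bundle.genes}).to_csv(row_meta, index=False)
    meta = bundle.sample_meta.reset_index()
    meta = meta.rename(columns={meta.columns[0]: "sample"})
    meta.to_csv(col_meta, index=False, float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# Interaction network
# ---------------------------------------------------------------------------


@dataclass
class InteractionNetwork:
    """Undirected weighted gene-gene network with confidences in [0, 1].

    ``edges`` has columns ``gene_a``, ``gene_b``, ``score`` with
    ``gene_a < gene_b`` lexicographically (no self-loops, no duplicate
    unordered pairs); ``nodes`` is the sorted node list and may contain
    isolated genes.
    """

    edges: pd.DataFrame
    nodes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.nodes:
            self.nodes = sorted(
                set(self.edges["gene_a"]) | set(self.edges["gene_b"])
            )
        self.validate()

    def validate(self) -> None:
        e = self.edges
        for col in ("gene_a", "gene_b", "score"):
            if col not in e.columns:
                raise MissingColumnError(f"edge table lacks column {col!r}")
        if len(e):
            if (e["gene_a"] == e["gene_b"]).any():
                raise ValidationError("self-loop present in edge table")
            if not (e["gene_a"] < e["gene_b"]).all():
                raise ValidationError("edges must be stored with gene_a < gene_b")
            keys = e["gene_a"] + "\x00" + e["gene_b"]
            if keys.duplicated().any():
                raise ValidationError("duplicate unordered gene pair in edge table")
            s = e["score"].to_numpy(float)
            if not np.all((s >= 0) & (s <= 1)):
                raise ValidationError("edge scores must lie in [0, 1]")
        node_set = set(self.nodes)
        if len(e) and not (
            e["gene_a"].isin(node_set).all() and e["gene_b"].isin(node_set).all()
        ):
            raise ValidationError("edge endpoints missing from node list")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @classmethod
    def from_arrays(cls, gene_a, gene_b, score, nodes=None) -> "InteractionNetwork":
        """Build a network, dropping self-loops and collapsing duplicate
        unordered pairs to the maximum score (with a logged warning)."""
        a = np.asarray(gene_a, dtype=object)
        b = np.asarray(gene_b, dtype=object)
        s = np.asarray(score, dtype=float)
        lo = np.minimum(a, b)
        hi = np.maximum(a, b)
        keep = lo != hi
        n_self = int((~keep).sum())
        if n_self:
            logger.info("dropped %d self-loop edge(s)", n_self)
        df = pd.DataFrame({"gene_a": lo[keep], "gene_b": hi[keep], "score": s[keep]})
        n_raw = len(df)
        df = df.groupby(["gene_a", "gene_b"], as_index=False, sort=True)["score"].max()
        if len(df) < n_raw:
            logger.warning(
                "collapsed %d duplicate unordered pair(s) to their maximum score",
                n_raw - len(df),
            )
        if nodes is None:
            nodes = sorted(set(a[keep]) | set(b[keep]))
        else:
            nodes = sorted(set(nodes) | set(df["gene_a"]) | set(df["gene_b"]))
        return cls(edges=df, nodes=list(nodes))

    def to_networkx(self, weighted: bool = True):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        if weighted:
            g.add_weighted_edges_from(
                self.edges[["gene_a", "gene_b", "score"]].itertuples(index=False)
            )
        else:
            g.add_edges_from(self.edges[["gene_a", "gene_b"]].itertuples(index=False))
        return g


def read_edge_list(file, score_scale: str = "unit") -> InteractionNetwork:
    """Read a whitespace/tab-delimited ``geneA geneB score`` edge list.

    ``score_scale="milli"`` declares raw 0-999 confidence integers, which are
    divided by 1000; ``"unit"`` declares scores already in [0, 1].  A header
    row (non-numeric third field) is tolerated and skipped; extra columns are
    ignored.
    """
    if score_scale not in ("unit", "milli"):
        raise ValidationError(f"score_scale must be 'unit' or 'milli', got {score_scale!r}")
    hi = 1.0 if score_scale == "unit" else 999.0
    ga, gb, sc = [], [], []
    with open(file, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) < 3:
                raise FormatError(
                    f"{file}:{lineno}: expected at least 3 columns, got {len(parts)}"
                )
            try:
                s = float(parts[2])
            except ValueError:
                if lineno == 1:  # header row
                    continue
                raise FormatError(f"{file}:{lineno}: non-numeric score {parts[2]!r}")
            if not (0.0 <= s <= hi):
                raise FormatError(
                    f"{file}:{lineno}: score {s} outside declared range [0, {hi:g}]"
                )
            ga.append(parts[0])
            gb.append(parts[1])
            sc.append(s / 1000.0 if score_scale == "milli" else s)
    return InteractionNetwork.from_arrays(ga, gb, sc)


def write_edge_list(net: InteractionNetwork, file) -> None:
    """Write an edge list on the unit score scale (round-trips with
    :func:`read_edge_list`).  Isolated nodes are not representable in the
    edge-list format and are dropped on a round trip."""
    out = net.edges.copy()
    out["score"] = [FLOAT_FORMAT % v for v in out["score"]]
    out.to_csv(file, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# Gene tables
# ---------------------------------------------------------------------------


def read_gene_table(file, required: tuple[str, ...] | list[str] | None = None) -> pd.DataFrame:
    """Read a TSV gene table into a DataFrame indexed by unique gene id.

    ``NA`` is the missing-value token.  Raises on a missing ``gene`` column,
    a missing required column, or duplicated gene identifiers.
    """
    df = pd.read_csv(file, sep="\t", na_values=[NA_TOKEN], keep_default_na=False)
    if "gene" not in df.columns:
        raise MissingColumnError(f"{file}: gene table lacks a 'gene' column")
    for col in required or ():
        if col not in df.columns:
            raise MissingColumnError(f"{file}: gene table lacks required column {col!r}")
    df["gene"] = df["gene"].astype(str)
    if df["gene"].duplicated().any():
        dup = df["gene"][df["gene"].duplicated()].iloc[0]
        raise DuplicateGeneError(f"{file}: duplicated gene {dup!r}")
    return df.set_index("gene")


def write_gene_table(table: pd.DataFrame, file) -> None:
    """Write a gene-indexed DataFrame as TSV; floats keep 12 significant
    digits and missing values are serialized as ``NA``."""
    if not table.index.is_unique:
        dup = table.index[table.index.duplicated()][0]
        raise DuplicateGeneError(f"duplicated gene {dup!r}")
    out = table.copy()
    out.index.name = "gene"
    out.to_csv(
        file, sep="\t", na_rep=NA_TOKEN, float_format=FLOAT_FORMAT, lineterminator="\n"
    )


# ---------------------------------------------------------------------------
# DNM tables
# ---------------------------------------------------------------------------


def validate_dnm_table(dnm: pd.DataFrame) -> pd.DataFrame:
    """Validate and canonicalize a de novo mutation table.

    Requires columns ``gene``, ``individual``, ``cohort``, ``consequence``;
    consequence restricted to LOF / missense / synonymous; duplicate
    (gene, individual, consequence) records collapsed to one row.
    """
    for col in ("gene", "individual", "cohort", "consequence"):
        if col not in dnm.columns:
            raise MissingColumnError(f"DNM table lacks column {col!r}")
    bad = ~dnm["consequence"].isin(CONSEQUENCE_CLASSES)
    if bad.any():
        raise FormatError(
            f"invalid consequence class {dnm['consequence'][bad].iloc[0]!r} "
            f"(expected one of {CONSEQUENCE_CLASSES})"
        )
    out = dnm.drop_duplicates(subset=["gene", "individual", "consequence"], keep="first")
    return out.reset_index(drop=True)


def read_dnm_table(file) -> pd.DataFrame:
    df = pd.read_csv(file, sep="\t", dtype=str, na_values=[NA_TOKEN], keep_default_na=False)
    return validate_dnm_table(df)


def write_dnm_table(dnm: pd.DataFrame, file) -> None:
    validate_dnm_table(dnm).to_csv(file, sep="\t", index=False, na_rep=NA_TOKEN, lineterminator="\n")


# ---------------------------------------------------------------------------
# eQTL / GWAS tables
# ---------------------------------------------------------------------------


def validate_eqtl_table(table: pd.DataFrame) -> pd.DataFrame:
    """Validate an eQTL table with columns ``snp``, ``gene``, ``gwas_p``."""
    for col in ("snp", "gene", "gwas_p"):
        if col not in table.columns:
            raise MissingColumnError(f"eQTL table lacks column {col!r}")
    p = table["gwas_p"].to_numpy(float)
    if not np.all((p > 0) & (p <= 1)):
        raise FormatError("gwas_p values must lie in (0, 1]")
    return table.reset_index(drop=True)


def read_eqtl_table(file) -> pd.DataFrame:
    df = pd.read_csv(file, sep="\t", na_values=[NA_TOKEN], keep_default_na=False)
    df = validate_eqtl_table(df)
    df["gene"] = df["gene"].astype(str)
    df["snp"] = df["snp"].astype(str)
    return df


def write_eqtl_table(table: pd.DataFrame, file) -> None:
    validate_eqtl_table(table).to_csv(
        file, sep="\t", index=False, na_rep=NA_TOKEN, float_format=FLOAT_FORMAT, lineterminator="\n"
    )
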