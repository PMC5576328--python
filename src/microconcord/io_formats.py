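"""Readers, writers and validated containers for every external format the
pipeline touches.

Supported on-disk representations:

* OTU count tables as plain tab-separated matrices (``#OTU ID`` header
  tolerated, QIIME-style leading comment lines skipped) or as BIOM 1.0 JSON
  (both ``sparse`` and ``dense`` matrix encodings).
* Taxonomy maps as two-column TSV (OTU id, semicolon-separated lineage).
  Both single- and double-underscore GreenGenes rank prefixes are accepted.
* Rooted phylogenies as newick (parsed with scikit-bio).
* Sample-pairing metadata as TSV with columns
  ``pair_id, induced_id, spontaneous_id, state``.
* Per-pair concordance reports as TSV plus a human-readable summary.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from io import StringIO
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

from .errors import FormatError

logger = logging.getLogger(__name__)

#: Rooted phylogeny with branch lengths; leaves index OTUs.
PhyloTree = TreeNode

RANK_PREFIXES = ("k", "p", "c", "o", "f", "g", "s")
VALID_STATES = ("stable", "exacerbation")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CountTable:
    """OTU x sample matrix of non-negative integer sequence counts.

    ``data`` is indexed by OTU id with sample ids as columns; order is
    preserved from the source file.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            raise FormatError("duplicate OTU ids in count table")
        if df.columns.has_duplicates:
            raise FormatError("duplicate sample ids in count table")
        values = df.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.number):
            raise FormatError("non-numeric cell in count table")
        if values.size:
            if np.any(values < 0):
                raise FormatError("negative count in count table")
            if not np.allclose(values, np.round(values)):
                raise FormatError("non-integral count in count table")
            object.__setattr__(
                self, "data", df.astype(np.int64, copy=False)
            )

    @property
    def otu_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def counts(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def column(self, sample_id: str) -> np.ndarray:
        return self.data[sample_id].to_numpy()


@dataclass(frozen=True)
class TaxaTable:
    """Taxon x sample table produced by collapsing OTUs at a rank.

    Taxon labels are full lineage prefixes, e.g.
    ``k_Bacteria;...;f_Gemellaceae;g_`` for an unnamed genus.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise FormatError("duplicate taxon labels")
        if self.data.columns.has_duplicates:
            raise FormatError("duplicate sample ids")

    @property
    def taxon_labels(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)


@dataclass(frozen=True)
class TaxonomyMap:
    """Mapping from OTU id to a normalized lineage of up to 7 rank labels."""

    entries: Mapping[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        for otu, lineage in self.entries.items():
            if not 1 <= len(lineage) <= 7:
                raise FormatError(
                    f"lineage for {otu!r} has {len(lineage)} ranks (must be 1-7)"
                )

    def lineage(self, otu_id: str) -> tuple[str, ...] | None:
        return self.entries.get(otu_id)


@dataclass(frozen=True)
class PairRecord:
    pair_id: str
    induced_id: str
    spontaneous_id: str
    state: str


@dataclass(frozen=True)
class SamplePairing:
    """The (induced, spontaneous, state) triples defining paired comparisons."""

    pairs: tuple[PairRecord, ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.pairs:
            if rec.state not in VALID_STATES:
                raise FormatError(
                    f"unknown state {rec.state!r} for pair {rec.pair_id!r}"
                )
            if rec.induced_id == rec.spontaneous_id:
                raise FormatError(
                    f"pair {rec.pair_id!r} lists the same sample twice"
                )
            for sid in (rec.induced_id, rec.spontaneous_id):
                if sid in seen:
                    raise FormatError(f"sample {sid!r} appears in two pairs")
                seen.add(sid)

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    def subset(self, state: str) -> "SamplePairing":
        """Pairs whose disease state matches; ``state='all'`` returns all."""
        if state == "all":
            return self
        if state not in VALID_STATES:
            raise FormatError(f"unknown state {state!r}")
        return SamplePairing(
            tuple(p for p in self.pairs if p.state == state)
        )

    def sample_ids(self) -> list[str]:
        out: list[str] = []
        for p in self.pairs:
            out.extend((p.induced_id, p.spontaneous_id))
        return out

    def state_counts(self) -> dict[str, int]:
        counts = {s: 0 for s in VALID_STATES}
        for p in self.pairs:
            counts[p.state] += 1
        return counts

    def validate_against(self, table: CountTable) -> None:
        missing = set(self.sample_ids()) - set(table.sample_ids)
        if missing:
            raise FormatError(
                f"paired samples missing from count table: {sorted(missing)}"
            )


# ---------------------------------------------------------------------------
# lineage parsing
# ---------------------------------------------------------------------------

def parse_lineage(lineage: str) -> tuple[str, ...]:
    """Split a GreenGenes-style lineage string into normalized rank labels.

    Accepts both ``g__Name`` and ``g_Name`` prefixes as well as bare names
    (prefixed by rank position); empty labels are kept as bare prefixes
    (``g_``), matching the convention for unnamed genera.
    """
    tokens = [t.strip() for t in lineage.split(";")]
    # trailing separator produces one empty trailing token; drop it
    while tokens and tokens[-1] == "" and len(tokens) > 7:
        tokens.pop()
    if len(tokens) > 7:
        raise FormatError(f"lineage has more than 7 ranks: {lineage!r}")
    normalized = []
    for i, tok in enumerate(tokens):
        prefix = RANK_PREFIXES[i] if i < len(RANK_PREFIXES) else "x"
        if tok.startswith(prefix + "__"):
            name = tok[len(prefix) + 2:]
        elif tok.startswith(prefix + "_"):
            name = tok[len(prefix) + 1:]
        else:
            name = tok
        normalized.append(f"{prefix}_{name}")
    return tuple(normalized)


# ---------------------------------------------------------------------------
# count tables
# ---------------------------------------------------------------------------

def read_count_table(path: str | Path, dialect: str = "tsv") -> CountTable:
    """Read an OTU count table from ``tsv`` or ``biom_json``."""
    path = Path(path)
    if dialect == "tsv":
        return _read_count_tsv(path)
    if dialect == "biom_json":
        return _read_biom_json(path)
    raise FormatError(f"unknown count-table dialect {dialect!r}")


def _read_count_tsv(path: Path) -> CountTable:
    lines = path.read_text().splitlines()
    # QIIME writes "# Constructed from biom file" before the header
    body = [
        ln for ln in lines
        if ln.strip() and not (ln.startswith("#") and not ln.startswith("#OTU ID"))
    ]
    if not body:
        raise FormatError(f"{path}: empty count table")
    header = body[0].split("\t")[1:]
    if len(header) != len(set(header)):
        raise FormatError(f"{path}: duplicate sample ids in header")
    try:
        df = pd.read_csv(StringIO("\n".join(body)), sep="\t", index_col=0)
    except Exception as exc:  # malformed table
        raise FormatError(f"{path}: cannot parse tsv count table: {exc}") from exc
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns = df.columns.astype(str)
    try:
        return CountTable(df)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_count_table(
    table: CountTable, path: str | Path, dialect: str = "tsv"
) -> None:
    path = Path(path)
    if dialect == "tsv":
        with open(path, "w") as fh:
            fh.write("#OTU ID\t" + "\t".join(table.sample_ids) + "\n")
            table.data.to_csv(fh, sep="\t", header=False)
    elif dialect == "biom_json":
        _write_biom_json(table, path)
    else:
        raise FormatError(f"unknown count-table dialect {dialect!r}")


def _read_biom_json(path: Path) -> CountTable:
    with open(path) as fh:
        doc = json.load(fh)
    for key in ("rows", "columns", "shape", "data", "matrix_type"):
        if key not in doc:
            raise FormatError(f"{path}: BIOM document missing {key!r}")
    n_rows, n_cols = doc["shape"]
    otu_ids = [str(r["id"]) for r in doc["rows"]]
    sample_ids = [str(c["id"]) for c in doc["columns"]]
    if len(otu_ids) != n_rows or len(sample_ids) != n_cols:
        raise FormatError(f"{path}: BIOM shape disagrees with row/column lists")
    mat = np.zeros((n_rows, n_cols), dtype=float)
    mtype = doc["matrix_type"]
    if mtype == "sparse":
        for i, j, v in doc["data"]:
            mat[int(i), int(j)] = v
    elif mtype == "dense":
        mat = np.asarray(doc["data"], dtype=float)
        if mat.shape != (n_rows, n_cols):
            raise FormatError(f"{path}: dense BIOM data has wrong shape")
    else:
        raise FormatError(f"{path}: unsupported matrix_type {mtype!r}")
    df = pd.DataFrame(mat, index=otu_ids, columns=sample_ids)
    try:
        return CountTable(df)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def _write_biom_json(table: CountTable, path: Path) -> None:
    counts = table.counts
    rows, cols = np.nonzero(counts)
    doc = {
        "id": None,
        "format": "Biological Observation Matrix 1.0.0",
        "format_url": "http://biom-format.org",
        "type": "OTU table",
        "generated_by": "microconcord",
        "date": "",
        "matrix_type": "sparse",
        "matrix_element_type": "int",
        "shape": list(table.shape),
        "rows": [{"id": o, "metadata": None} for o in table.otu_ids],
        "columns": [{"id": s, "metadata": None} for s in table.sample_ids],
        "data": [
            [int(i), int(j), int(counts[i, j])] for i, j in zip(rows, cols)
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


# ---------------------------------------------------------------------------
# taxonomy
# ---------------------------------------------------------------------------

def read_taxonomy(path: str | Path) -> TaxonomyMap:
    """Read a two-column (OTU id, lineage) TSV into a TaxonomyMap."""
    entries: dict[str, tuple[str, ...]] = {}
    for ln in Path(path).read_text().splitlines():
        if not ln.strip() or ln.startswith("#"):
            continue
        fields = ln.split("\t")
        if len(fields) < 2:
            raise FormatError(f"taxonomy line has <2 columns: {ln!r}")
        otu = fields[0].strip()
        if otu in entries:
            raise FormatError(f"duplicate taxonomy entry for OTU {otu!r}")
        entries[otu] = parse_lineage(fields[1])
    return TaxonomyMap(entries)


def write_taxonomy(tax: TaxonomyMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for otu, lineage in tax.entries.items():
            fh.write(f"{otu}\t{';'.join(lineage)}\n")


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

def read_newick(path: str | Path) -> PhyloTree:
    """Parse a rooted newick tree; missing branch lengths become 0."""
    try:
        tree = TreeNode.read(str(path), format="newick")
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse newick: {exc}") from exc
    return _validate_tree(tree)


def read_newick_string(newick: str) -> PhyloTree:
    try:
        tree = TreeNode.read(StringIO(newick), format="newick")
    except Exception as exc:
        raise FormatError(f"cannot parse newick: {exc}") from exc
    return _validate_tree(tree)


def _validate_tree(tree: TreeNode) -> TreeNode:
    names = [t.name for t in tree.tips()]
    if len(names) != len(set(names)):
        raise FormatError("duplicate leaf names in tree")
    n_missing = 0
    for node in tree.traverse(include_self=True):
        if node.length is None:
            node.length = 0.0
            n_missing += 1
        elif node.length < 0:
            raise FormatError("negative branch length in tree")
    if n_missing:
        logger.warning("tree: %d missing branch lengths read as 0", n_missing)
    return tree


def write_newick(tree: PhyloTree, path: str | Path) -> None:
    tree.write(str(path), format="newick")


def total_branch_length(tree: PhyloTree) -> float:
    return sum(
        node.length or 0.0 for node in tree.traverse(include_self=True)
    )


# ---------------------------------------------------------------------------
# pairing metadata
# ---------------------------------------------------------------------------

def read_pairing(path: str | Path) -> SamplePairing:
    """Read pairing metadata (pair_id, induced_id, spontaneous_id, state)."""
    lines = [
        ln for ln in Path(path).read_text().splitlines() if ln.strip()
    ]
    if not lines:
        return SamplePairing(())
    header = [h.strip().lstrip("#") for h in lines[0].split("\t")]
    required = ["pair_id", "induced_id", "spontaneous_id", "state"]
    if set(required) - set(header):
        raise FormatError(
            f"pairing file must have columns {required}, got {header}"
        )
    idx = {name: header.index(name) for name in required}
    records = []
    for ln in lines[1:]:
        fields = [f.strip() for f in ln.split("\t")]
        records.append(
            PairRecord(
                pair_id=fields[idx["pair_id"]],
                induced_id=fields[idx["induced_id"]],
                spontaneous_id=fields[idx["spontaneous_id"]],
                state=fields[idx["state"]],
            )
        )
    return SamplePairing(tuple(records))


def write_pairing(pairing: SamplePairing, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("pair_id\tinduced_id\tspontaneous_id\tstate\n")
        for p in pairing:
            fh.write(
                f"{p.pair_id}\t{p.induced_id}\t{p.spontaneous_id}\t{p.state}\n"
            )


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

REPORT_COLUMNS = [
    "pair_id",
    "state",
    "one_minus_theta_all",
    "one_minus_theta_dom",
    "mean_diff",
    "loa_lower",
    "loa_upper",
    "loa_range",
    "theta_discordant_all",
    "theta_discordant_dom",
    "loa_discordant",
]


def write_report(results: Sequence, path: str | Path) -> pd.DataFrame:
    """Write per-pair concordance results to TSV at full float precision.

    ``results`` is a sequence of objects exposing the REPORT_COLUMNS fields
    (see ``concordance_stats.PairConcordanceResult``). Returns the frame
    written so callers can render a summary.
    """
    rows = []
    for r in results:
        rows.append({c: getattr(r, c) for c in REPORT_COLUMNS})
    df = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    # default float formatting is shortest round-trip repr, so re-reading
    # the tsv reproduces every value exactly
    df.to_csv(path, sep="\t", index=False)
    return df


def read_report(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
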