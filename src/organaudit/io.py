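"""Plain-text I/O: FASTA, two-column taxonomy TSV, feature-table TSV, metadata.

All formats interoperate with common amplicon tooling: taxonomy files are
two-column (feature id, lineage string) TSVs, feature tables carry a
``#OTU ID`` header cell with sample ids as columns, and metadata files use a
``#SampleID`` first column. A ``#dialect=silva|greengenes`` comment line in
taxonomy files records the lineage dialect.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

FASTA_WIDTH = 80

_IUPAC_DNA = set("ACGTRYSWKMBDHVN")


@dataclass
class SequenceRecord:
    """A named DNA sequence; stored uppercase, U mapped to T on ingest."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self):
        if not self.id:
            raise ValueError("sequence record id must be non-empty")
        seq = self.seq.upper().replace("U", "T")
        if len(seq) == 0:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(seq) - _IUPAC_DNA
        if bad:
            raise ValueError(f"record {self.id!r}: non-IUPAC characters {sorted(bad)}")
        self.seq = seq


class ParseError(ValueError):
    pass


def read_fasta(path) -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecords (uppercased, U→T).

    Raises :class:`ParseError` for sequence data before the first header
    (naming the line) and for duplicate ids (listing them).
    """
    records: list[SequenceRecord] = []
    cur_id = None
    cur_desc = ""
    cur_seq: list[str] = []

    def flush():
        if cur_id is not None:
            records.append(SequenceRecord(cur_id, "".join(cur_seq), cur_desc))

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].strip()
                cur_id, _, cur_desc = header.partition(" ")
                if not cur_id:
                    raise ParseError(f"{path}: empty FASTA header at line {lineno}")
                cur_seq = []
            else:
                if cur_id is None:
                    raise ParseError(
                        f"{path}: sequence data before first '>' header at line {lineno}"
                    )
                cur_seq.append(line.strip())
    flush()
    ids = [r.id for r in records]
    dupes = sorted({i for i in ids if ids.count(i) > 1})
    if dupes:
        raise ParseError(f"{path}: duplicate sequence ids {dupes}")
    return records


def write_fasta(records, path, width: int = FASTA_WIDTH) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i:i + width] + "\n")


def read_taxonomy_table(path) -> dict[str, str]:
    """Read a two-column (id, lineage string) TSV into a dict.

    Header rows whose first cell starts with ``Feature ID`` or ``#`` are
    skipped; extra columns are ignored.
    """
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            first = line.split("\t", 1)[0]
            if first.startswith("#") or first.startswith("Feature ID"):
                continue
            cols = line.split("\t")
            if len(cols) < 2:
                raise ParseError(f"{path}: row {lineno} has fewer than 2 columns")
            fid = cols[0].strip()
            if fid in out:
                raise ParseError(f"{path}: duplicate feature id {fid!r} at row {lineno}")
            out[fid] = cols[1].strip()
    return out


def read_taxonomy_dialect(path) -> str | None:
    """Return the dialect recorded in a ``#dialect=`` comment, if any."""
    with open(path) as fh:
        for line in fh:
            if line.startswith("#dialect="):
                return line.strip().split("=", 1)[1]
            if not line.startswith("#"):
                break
    return None


def write_taxonomy_table(mapping: dict[str, str], path, dialect: str | None = None,
                         header: bool = False) -> None:
    """Write id→lineage pairs as a TSV, optionally with a dialect comment."""
    with open(path, "w") as fh:
        if dialect is not None:
            fh.write(f"#dialect={dialect}\n")
        if header:
            fh.write("Feature ID\tTaxon\n")
        for fid, lin in mapping.items():
            fh.write(f"{fid}\t{lin}\n")


# ---------------------------------------------------------------------------
# feature tables (features x samples, integer counts) and sample metadata

def validate_feature_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check feature-table invariants; returns the table with int counts."""
    if table.shape[1] < 1:
        raise ValueError("feature table must have at least one sample")
    if table.index.has_duplicates:
        dupes = sorted(table.index[table.index.duplicated()].unique())
        raise ValueError(f"duplicate feature ids {dupes}")
    if table.columns.has_duplicates:
        raise ValueError("duplicate sample ids")
    values = table.to_numpy()
    if (values < 0).any():
        raise ValueError("feature table contains negative counts")
    if not (values == values.astype(int)).all():
        raise ValueError("feature table contains non-integer counts")
    return table.astype(int)


def read_feature_table(path) -> pd.DataFrame:
    """Read a ``#OTU ID``-headed TSV feature table (features × samples)."""
    table = pd.read_csv(path, sep="\t", index_col=0)
    table.index.name = "#OTU ID"
    return validate_feature_table(table)


def write_feature_table(table: pd.DataFrame, path) -> None:
    out = table.copy()
    out.index.name = "#OTU ID"
    out.to_csv(path, sep="\t")


def read_metadata(path) -> pd.DataFrame:
    """Read a sample-metadata TSV keyed on its ``#SampleID`` first column."""
    md = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    md.index = md.index.astype(str)
    return md


def write_metadata(md: pd.DataFrame, path) -> None:
    out = md.copy()
    out.index.name = "#SampleID"
    out.to_csv(path, sep="\t")
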