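"""Reference taxonomies: amplicon extraction and organelle extension.

The central object is :class:`ReferenceDB`, a mapping of sequence id to
(sequence, lineage) with per-entry provenance (``base`` entries from a
standard release vs ``added`` organelle sequences). ``extend_reference``
produces an *extended* reference: organelle rRNA sequences are trimmed to
the amplified region with an in-silico PCR step and inserted under the
dialect's canonical organelle lineage, so that divergent mitochondrial and
chloroplast amplicons classify as organelles instead of surfacing as
"Unassigned".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .io import (SequenceRecord, read_fasta, read_taxonomy_dialect,
                 read_taxonomy_table, write_fasta, write_taxonomy_table)
from .lineage import Lineage, format_lineage, organelle_lineage, parse_lineage

logger = logging.getLogger(__name__)

IUPAC_SETS = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"), "R": frozenset("AG"), "Y": frozenset("CT"),
    "S": frozenset("CG"), "W": frozenset("AT"), "K": frozenset("GT"),
    "M": frozenset("AC"), "B": frozenset("CGT"), "D": frozenset("AGT"),
    "H": frozenset("ACT"), "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

#: V4 primers as printed in the study protocol this toolkit audits
DEFAULT_PRIMER_F = "GTGTGCCAGCMGCCGCGGTAA"   # 515f
DEFAULT_PRIMER_R = "GGACTACHVGGGTWTCTAAT"    # 806r


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def iupac_match(a: str, b: str) -> bool:
    """Two IUPAC codes match when their base sets intersect."""
    return bool(IUPAC_SETS[a] & IUPAC_SETS[b])


@dataclass(frozen=True)
class PrimerPair:
    """A degenerate primer pair with amplicon length bounds.

    ``reverse`` is given 5'→3' on the opposite strand, as conventionally
    written; its reverse complement is what is located downstream of the
    forward primer on the amplified strand.
    """

    forward: str = DEFAULT_PRIMER_F
    reverse: str = DEFAULT_PRIMER_R
    min_amplicon_len: int = 100
    max_amplicon_len: int = 500
    max_mismatch: int = 0

    def __post_init__(self):
        for name in ("forward", "reverse"):
            p = getattr(self, name).upper()
            if len(p) < 10:
                raise ValueError(f"{name} primer shorter than 10 nt")
            bad = set(p) - set(IUPAC_SETS)
            if bad:
                raise ValueError(f"{name} primer has non-IUPAC codes {sorted(bad)}")
            object.__setattr__(self, name, p)
        if not 0 < self.min_amplicon_len < self.max_amplicon_len:
            raise ValueError("need 0 < min_amplicon_len < max_amplicon_len")
        if self.max_mismatch < 0:
            raise ValueError("max_mismatch must be non-negative")


def _find_primer_sites(seq: str, primer: str, max_mismatch: int):
    """Yield start positions where primer matches with ≤ max_mismatch mismatches."""
    m = len(primer)
    for i in range(len(seq) - m + 1):
        mism = 0
        for j in range(m):
            if not iupac_match(primer[j], seq[i + j]):
                mism += 1
                if mism > max_mismatch:
                    break
        else:
            yield i


def extract_amplicon(rec: SequenceRecord, primers: PrimerPair,
                     trunc_len: int | None = None) -> SequenceRecord | None:
    """In-silico PCR: return the inter-primer subsequence, or None.

    The forward primer is located on either strand (forward strand tried
    first); on the primer-bearing strand the reverse complement of the
    reverse primer is sought downstream. The leftmost forward site and the
    nearest downstream reverse site giving an in-bounds amplicon win. With
    ``trunc_len`` the amplicon is cut to its first ``trunc_len`` nt and
    shorter amplicons are rejected.
    """
    rc_rev = reverse_complement(primers.reverse)
    for strand_seq in (rec.seq, reverse_complement(rec.seq)):
        for fstart in _find_primer_sites(strand_seq, primers.forward,
                                         primers.max_mismatch):
            amp_start = fstart + len(primers.forward)
            for rstart in _find_primer_sites(strand_seq[amp_start:], rc_rev,
                                             primers.max_mismatch):
                amp = strand_seq[amp_start:amp_start + rstart]
                if primers.min_amplicon_len <= len(amp) <= primers.max_amplicon_len:
                    if trunc_len is not None:
                        if len(amp) < trunc_len:
                            return None
                        amp = amp[:trunc_len]
                    return SequenceRecord(rec.id, amp, rec.description)
                if len(amp) > primers.max_amplicon_len:
                    break
            break  # leftmost forward site only, per strand
    return None


@dataclass
class ReferenceDB:
    """id → (sequence, lineage) with provenance, in a single lineage dialect."""

    dialect: str
    entries: dict[str, tuple[SequenceRecord, Lineage]] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for fid, (rec, lin) in self.entries.items():
            if lin.dialect != self.dialect:
                raise ValueError(f"entry {fid!r} lineage dialect {lin.dialect!r} "
                                 f"differs from db dialect {self.dialect!r}")
            self.provenance.setdefault(fid, "base")

    def __len__(self):
        return len(self.entries)

    def __contains__(self, fid):
        return fid in self.entries

    def add(self, rec: SequenceRecord, lin: Lineage, provenance: str = "base") -> None:
        if rec.id in self.entries:
            raise ValueError(f"duplicate id {rec.id!r}")
        if lin.dialect != self.dialect:
            lin = lin.with_dialect(self.dialect)
        self.entries[rec.id] = (rec, lin)
        self.provenance[rec.id] = provenance

    def ids(self):
        return list(self.entries)

    def record(self, fid) -> SequenceRecord:
        return self.entries[fid][0]

    def lineage(self, fid) -> Lineage:
        return self.entries[fid][1]

    def copy(self) -> "ReferenceDB":
        return ReferenceDB(self.dialect, dict(self.entries), dict(self.provenance))

    def organelle_counts(self) -> dict[str, int]:
        """Counts of mitochondrial / chloroplast entries (Fig-2-style audit)."""
        mito = sum(lin.is_mitochondrion for _, lin in self.entries.values())
        chloro = sum(lin.is_chloroplast for _, lin in self.entries.values())
        return {"mitochondria": mito, "chloroplast": chloro}


def build_reference(records, taxonomy: dict[str, str], dialect: str) -> ReferenceDB:
    """Assemble a ReferenceDB from sequences and raw lineage strings."""
    db = ReferenceDB(dialect)
    for rec in records:
        if rec.id not in taxonomy:
            raise ValueError(f"no taxonomy for sequence {rec.id!r}")
        db.add(rec, parse_lineage(taxonomy[rec.id], dialect))
    return db


def extend_reference(base: ReferenceDB, organelle, kind: str, primers: PrimerPair,
                     host_labels: dict | None = None,
                     trunc_len: int | None = None) -> ReferenceDB:
    """Insert amplicon-extracted organelle sequences into a copy of ``base``.

    Each organelle record is trimmed to the amplified region (records with
    no in-bounds amplicon are skipped and counted), labelled with the
    dialect's canonical organelle lineage (host genus/species appended when
    supplied), and inserted with provenance ``added``. A record whose
    extracted sequence and lineage both already exist is skipped; id
    collisions are resolved with a ``.dupN`` suffix so divergent evidence is
    never silently dropped.
    """
    if kind not in ("mitochondria", "chloroplast"):
        raise ValueError(f"kind must be 'mitochondria' or 'chloroplast', got {kind!r}")
    out = base.copy()
    existing_pairs = {(rec.seq, format_lineage(lin))
                      for rec, lin in out.entries.values()}
    n_in = n_extracted = n_added = n_skipped = 0
    for rec in organelle:
        n_in += 1
        amp = extract_amplicon(rec, primers, trunc_len=trunc_len)
        if amp is None:
            continue
        n_extracted += 1
        host = host_labels.get(rec.id) if host_labels else None
        lin = organelle_lineage(kind, base.dialect, host=host)
        key = (amp.seq, format_lineage(lin))
        if key in existing_pairs:
            n_skipped += 1
            continue
        new_id = amp.id
        if new_id in out.entries:
            n = 1
            while f"{amp.id}.dup{n}" in out.entries:
                n += 1
            new_id = f"{amp.id}.dup{n}"
            logger.warning("id collision for %r; inserting as %r", amp.id, new_id)
        out.add(SequenceRecord(new_id, amp.seq, rec.description), lin,
                provenance="added")
        existing_pairs.add(key)
        n_added += 1
    logger.info("extend_reference(%s): n_in=%d n_extracted=%d n_added=%d n_skipped=%d",
                kind, n_in, n_extracted, n_added, n_skipped)
    out.extend_summary = {"n_in": n_in, "n_extracted": n_extracted,
                          "n_added": n_added, "n_skipped": n_skipped}
    return out


def write_reference(db: ReferenceDB, prefix) -> tuple[str, str]:
    """Write ``<prefix>.fasta`` and ``<prefix>.tax.tsv`` (lexicographic id order)."""
    fasta_path = f"{prefix}.fasta"
    tax_path = f"{prefix}.tax.tsv"
    order = sorted(db.entries)
    write_fasta([db.record(i) for i in order], fasta_path)
    tax = {i: format_lineage(db.lineage(i)) for i in order}
    write_taxonomy_table(tax, tax_path, dialect=db.dialect)
    return fasta_path, tax_path


def read_reference(prefix, dialect: str | None = None) -> ReferenceDB:
    """Read a reference written by :func:`write_reference`."""
    tax_path = f"{prefix}.tax.tsv"
    if dialect is None:
        dialect = read_taxonomy_dialect(tax_path)
        if dialect is None:
            raise ValueError(f"{tax_path}: no #dialect comment and no dialect given")
    records = read_fasta(f"{prefix}.fasta")
    taxonomy = read_taxonomy_table(tax_path)
    return build_reference(records, taxonomy, dialect)
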