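"""Taxonomic lineage strings in SILVA and Greengenes dialects.

A lineage is an ordered list of labels for the seven canonical ranks
(domain, phylum, class, order, family, genus, species). SILVA prefixes the
domain rank with ``d__`` and omits trailing empty ranks; Greengenes uses
``k__`` and pads every rank with a bare prefix. Organelle status
(mitochondrion / chloroplast) is derived from the labels themselves by a
case-insensitive token match, so audits behave identically in both dialects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")
N_RANKS = len(RANKS)

#: literal used (in both dialects) for a read with no domain-level assignment
UNASSIGNED = "Unassigned"

_PREFIXES = {
    "silva": ("d__", "p__", "c__", "o__", "f__", "g__", "s__"),
    "greengenes": ("k__", "p__", "c__", "o__", "f__", "g__", "s__"),
}

#: where each base release files organelles; host genus/species may be appended
ORGANELLE_PARENT_LABELS = {
    ("silva", "mitochondria"): (
        "Bacteria", "Proteobacteria", "Alphaproteobacteria", "Rickettsiales",
        "Mitochondria",
    ),
    ("silva", "chloroplast"): (
        "Bacteria", "Cyanobacteria", "Cyanobacteriia", "Chloroplast",
    ),
    ("greengenes", "mitochondria"): (
        "Bacteria", "Proteobacteria", "Alphaproteobacteria", "Rickettsiales",
        "mitochondria",
    ),
    ("greengenes", "chloroplast"): (
        "Bacteria", "Cyanobacteria", "Chloroplast",
    ),
}


def _check_dialect(dialect: str) -> None:
    if dialect not in _PREFIXES:
        raise ValueError(f"unknown dialect {dialect!r}; expected 'silva' or 'greengenes'")


@dataclass(frozen=True)
class Lineage:
    """An ordered 7-rank taxonomic assignment with derived organelle flags."""

    labels: tuple[str, ...]
    dialect: str = "silva"

    def __post_init__(self):
        _check_dialect(self.dialect)
        labels = tuple(str(x).strip() for x in self.labels)
        if len(labels) > N_RANKS:
            raise ValueError(f"lineage has {len(labels)} ranks; at most {N_RANKS} allowed")
        labels = labels + ("",) * (N_RANKS - len(labels))
        seen_empty = False
        for lab in labels:
            if lab == "":
                seen_empty = True
            elif seen_empty:
                raise ValueError(f"gap in lineage: non-empty label after empty rank in {labels}")
        object.__setattr__(self, "labels", labels)
        lowered = {lab.lower() for lab in labels}
        if "mitochondria" in lowered and "chloroplast" in lowered:
            raise ValueError("lineage claims both mitochondrial and chloroplast "
                             f"identity: {labels}")

    # -- derived flags ---------------------------------------------------
    @property
    def is_mitochondrion(self) -> bool:
        return any(lab.lower() == "mitochondria" for lab in self.labels)

    @property
    def is_chloroplast(self) -> bool:
        return any(lab.lower() == "chloroplast" for lab in self.labels)

    @property
    def is_unassigned(self) -> bool:
        """True when nothing is assigned, even at domain level."""
        return self.labels[0] in ("", UNASSIGNED)

    @property
    def depth(self) -> int:
        """Number of non-empty ranks (0..7)."""
        n = 0
        for lab in self.labels:
            if lab == "":
                break
            n += 1
        return n

    def label_at(self, rank: str) -> str:
        return self.labels[RANKS.index(rank)]

    def truncated(self, depth: int) -> "Lineage":
        """Copy keeping only the first ``depth`` ranks."""
        return Lineage(self.labels[:depth], self.dialect)

    def with_dialect(self, dialect: str) -> "Lineage":
        return Lineage(self.labels, dialect)


def unassigned_lineage(dialect: str = "silva") -> Lineage:
    return Lineage((UNASSIGNED,), dialect)


def organelle_lineage(kind: str, dialect: str,
                      host: tuple[str, str] | None = None) -> Lineage:
    """Canonical lineage under which an added organelle sequence is filed.

    ``host`` optionally supplies (genus, species) labels of the organelle's
    host organism, appended at the genus/species ranks.
    """
    key = (dialect, kind)
    if key not in ORGANELLE_PARENT_LABELS:
        raise ValueError(f"unknown organelle kind {kind!r} for dialect {dialect!r}")
    labels = ORGANELLE_PARENT_LABELS[key]
    if host is not None:
        genus, species = host
        # propagate the organelle token down to the family rank so the
        # lineage stays gap-free, then file the host at genus/species
        organelle_token = labels[-1]
        pad = (organelle_token,) * (N_RANKS - 2 - len(labels))
        labels = labels + pad + (genus, species)
    return Lineage(labels, dialect)


def parse_lineage(raw: str, dialect: str) -> Lineage:
    """Parse a semicolon-separated lineage string in the given dialect.

    The bare sentinel ``"Unassigned"`` parses to a lineage whose domain slot
    holds that literal and whose organelle flags are false.
    """
    _check_dialect(dialect)
    raw = raw.strip()
    if raw == "" or raw == UNASSIGNED:
        return unassigned_lineage(dialect)
    fields = [f.strip() for f in raw.split(";")]
    # tolerate a trailing separator
    if fields and fields[-1] == "":
        fields = fields[:-1]
    if len(fields) > N_RANKS:
        raise ValueError(f"lineage {raw!r} has {len(fields)} rank fields; at most {N_RANKS}")
    prefixes = _PREFIXES[dialect]
    labels = []
    for i, f in enumerate(fields):
        if not f.startswith(prefixes[i]):
            raise ValueError(
                f"rank field {f!r} at position {i} lacks the {dialect} prefix {prefixes[i]!r}"
            )
        labels.append(f[len(prefixes[i]):].strip())
    # trailing bare prefixes parse to empty labels; Lineage enforces no gaps
    return Lineage(tuple(labels), dialect)


def format_lineage(lin: Lineage, dialect: str | None = None) -> str:
    """Format a lineage back to its dialect string.

    Greengenes pads empty tail ranks with bare prefixes; SILVA omits them.
    An all-empty (or sentinel) lineage formats as ``"Unassigned"``.
    """
    dialect = lin.dialect if dialect is None else dialect
    _check_dialect(dialect)
    if lin.is_unassigned:
        return UNASSIGNED
    prefixes = _PREFIXES[dialect]
    depth = lin.depth
    if dialect == "greengenes":
        fields = [prefixes[i] + lin.labels[i] for i in range(N_RANKS)]
    else:
        fields = [prefixes[i] + lin.labels[i] for i in range(depth)]
    return "; ".join(fields)
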