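"""Synthetic fixtures: hierarchical bacterial references, divergent organelle
pools with cryptic variants, toy three-microbe communities, multi-sample
studies with group-varying organelle load, shuffled artifacts, and
organelle-free mock communities.

The generator emulates the situation this toolkit audits: amplicon studies
where mitochondrial 12S amplicons co-amplify with bacterial 16S, some of the
mitochondrial variants are missing from the base reference ("cryptic"), and
the organelle load differs between sample groups even though the true
bacterial communities are exchangeable. All generators are pure functions of
(spec, seed).
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .align import semiglobal_align
from .io import SequenceRecord
from .lineage import Lineage, format_lineage
from .refdb import (DEFAULT_PRIMER_F, DEFAULT_PRIMER_R, IUPAC_SETS, PrimerPair,
                    ReferenceDB, reverse_complement)

_BASES = np.array(list("ACGT"))


@dataclass
class SimSpec:
    """Study conditions for the synthetic fixtures.

    Defaults encode the desk-scale benchmark: a 3×4×3 bacterial reference,
    a 12-variant organelle pool at 20% divergence with a quarter present in
    the base reference, and two 10-sample groups of 500 reads differing only
    in organelle load.
    """

    n_phyla: int = 3
    genera_per_phylum: int = 4
    species_per_genus: int = 3
    seq_len: int = 250
    within_genus_divergence: float = 0.03
    between_phylum_divergence: float = 0.30
    organelle_pool_size: int = 12
    organelle_divergence: float = 0.20
    base_db_organelle_fraction: float = 0.25
    n_samples_per_group: int = 10
    reads_per_sample: int = 500
    organelle_load_by_group: dict = field(
        default_factory=lambda: {"low": 0.05, "high": 0.30})
    sequencing_error_rate: float = 0.001
    dirichlet_concentration: float = 50.0
    cryptic_preference: float = 4.0   # sampling weight of cryptic vs in-base variants
    seed: int = 0

    def __post_init__(self):
        for name in ("within_genus_divergence", "between_phylum_divergence",
                     "organelle_divergence", "base_db_organelle_fraction",
                     "sequencing_error_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not self.within_genus_divergence < self.between_phylum_divergence:
            raise ValueError("within_genus_divergence must be < between_phylum_divergence")
        if self.reads_per_sample < 1:
            raise ValueError("reads_per_sample must be >= 1")
        for g, load in self.organelle_load_by_group.items():
            if not 0 <= load <= 1:
                raise ValueError(f"organelle load for group {g!r} outside [0, 1]")


@dataclass
class StudyTruth:
    """Ground truth for a generated fixture."""

    feature_origin: dict[str, tuple]      # feature id -> ("bacteria", lineage str)
                                          # or ("organelle", variant id, cryptic?)
    sample_group: dict[str, str]
    organelle_load: dict[str, float]      # realized per-sample organelle fraction

    def organelle_features(self) -> list[str]:
        return [f for f, o in self.feature_origin.items() if o[0] == "organelle"]

    def cryptic_features(self) -> list[str]:
        return [f for f, o in self.feature_origin.items()
                if o[0] == "organelle" and o[2]]


# ---------------------------------------------------------------------------
# sequence helpers

def _random_seq(rng, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _mutate(rng, seq: str, divergence: float) -> str:
    """Substitute ~divergence of positions, always to a different base."""
    arr = np.array(list(seq))
    n_mut = rng.binomial(len(arr), divergence)
    if n_mut == 0:
        return seq
    pos = rng.choice(len(arr), size=n_mut, replace=False)
    for p in pos:
        choices = [b for b in "ACGT" if b != arr[p]]
        arr[p] = choices[rng.integers(3)]
    return "".join(arr)


def _apply_errors(rng, seq: str, rate: float) -> str:
    return _mutate(rng, seq, rate) if rate > 0 else seq


def _feature_id(seq: str) -> str:
    return "asv_" + hashlib.md5(seq.encode()).hexdigest()[:12]


def _concrete_primer(rng, primer: str) -> str:
    """Resolve degenerate codes to one concrete base each."""
    return "".join(b if b in "ACGT" else sorted(IUPAC_SETS[b])[rng.integers(
        len(IUPAC_SETS[b]))] for b in primer)


# ---------------------------------------------------------------------------
# reference + tree

def generate_reference(spec: SimSpec) -> tuple[ReferenceDB, str]:
    """Hierarchical bacterial reference plus a matching newick tree.

    Phylum root sequences are independent uniform random; genus ancestors
    diverge from the root at half the between-phylum divergence and species
    from their genus ancestor at half the within-genus divergence, so
    within-genus pairs are ~``within_genus_divergence`` apart.
    """
    rng = np.random.default_rng(spec.seed)
    db = ReferenceDB("silva")
    phylum_clades = []
    genus_div = spec.between_phylum_divergence / 2
    species_div = spec.within_genus_divergence / 2
    for p in range(spec.n_phyla):
        root = _random_seq(rng, spec.seq_len)
        genus_clades = []
        for g in range(spec.genera_per_phylum):
            anc = _mutate(rng, root, genus_div)
            tips = []
            for s in range(spec.species_per_genus):
                seq = _mutate(rng, anc, species_div)
                fid = f"ref_p{p}g{g}s{s}"
                lin = Lineage(("Bacteria", f"Phylum_{p}", f"Class_{p}",
                               f"Order_{p}_{g}", f"Family_{p}_{g}",
                               f"Genus_{p}_{g}", f"Species_{p}_{g}_{s}"), "silva")
                db.add(SequenceRecord(fid, seq), lin)
                # quoted so newick readers keep the underscores
                tips.append(f"'{fid}':{species_div:.4f}")
            genus_clades.append(f"({','.join(tips)}):{genus_div:.4f}")
        phylum_clades.append(f"({','.join(genus_clades)}):0.2500")
    newick = f"({','.join(phylum_clades)})root;"
    return db, newick


# ---------------------------------------------------------------------------
# organelle pool

def generate_organelle_pool(spec: SimSpec, reference: ReferenceDB,
                            max_attempts: int = 100
                            ) -> tuple[list[SequenceRecord], list[str]]:
    """A pool of organelle amplicon variants radiating from a latent
    ancestral sequence far from all bacterial references (< 0.75 identity,
    rejection-sampled). Each variant diverges from the ancestor at the
    configured divergence, so any two variants are ~2x that far apart —
    emulating heteroplasmic / dietary mitochondrial diversity. Variants are
    wrapped in concrete V4 primer flanks so the reference extension's
    in-silico PCR applies. The first ⌈fraction × size⌉ ids form the base
    subset; the rest are the cryptic variants (absent from the base
    reference yet well beyond the consensus classifier's identity cutoff
    from everything it contains).
    """
    if spec.organelle_pool_size < 1:
        raise ValueError("organelle_pool_size must be >= 1")
    rng = np.random.default_rng(spec.seed + 1)
    ancestor = organelle_ancestor(spec, reference, max_attempts=max_attempts,
                                  rng=rng)
    f_primer = _concrete_primer(rng, DEFAULT_PRIMER_F)
    r_primer_rc = reverse_complement(_concrete_primer(rng, DEFAULT_PRIMER_R))
    cores = [_mutate(rng, ancestor, spec.organelle_divergence)
             for _ in range(spec.organelle_pool_size)]
    pool = [SequenceRecord(f"mito_{i:03d}", f_primer + core + r_primer_rc)
            for i, core in enumerate(cores)]
    n_base = math.ceil(spec.base_db_organelle_fraction * spec.organelle_pool_size)
    base_subset = [rec.id for rec in pool[:n_base]]
    return pool, base_subset


def organelle_ancestor(spec: SimSpec, reference: ReferenceDB,
                       max_attempts: int = 100, rng=None) -> str:
    """The latent ancestral organelle amplicon the pool radiates from.

    Deterministic given (spec, reference): calling this with the spec used
    for :func:`generate_organelle_pool` reproduces that pool's ancestor.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed + 1)
    ref_seqs = [reference.record(fid).seq for fid in reference.ids()]
    for _ in range(max_attempts):
        cand = _random_seq(rng, spec.seq_len)
        if all(semiglobal_align(cand, r).identity < 0.75 for r in ref_seqs):
            return cand
    raise RuntimeError("could not generate an organelle ancestor below "
                       "0.75 identity to the bacterial references")


def organelle_core(rec: SequenceRecord,
                   primers: PrimerPair | None = None) -> str:
    """Strip the primer flanks a pool record carries (the amplicon core)."""
    primers = primers or PrimerPair()
    return rec.seq[len(primers.forward):len(rec.seq) - len(primers.reverse)]


# ---------------------------------------------------------------------------
# the conceptual three-community example

def simulate_fig1_communities(organelle_counts: list[int] = (6, 3, 0),
                              n_microbes: int = 3
                              ) -> tuple[pd.DataFrame, StudyTruth]:
    """Communities with identical true microbiomes but varying mitochondrial
    load, split across two variants ("light"/"dark"). One read per microbial
    feature; community i carries organelle_counts[i] organelle reads.
    """
    if n_microbes < 1:
        raise ValueError("n_microbes must be >= 1")
    if any(m < 0 for m in organelle_counts):
        raise ValueError("organelle counts must be non-negative")
    samples = [f"community_{i}" for i in range(len(organelle_counts))]
    features = [f"microbe_{j}" for j in range(n_microbes)] + ["mito_light",
                                                              "mito_dark"]
    table = pd.DataFrame(0, index=features, columns=samples)
    for s, m in zip(samples, organelle_counts):
        for j in range(n_microbes):
            table.loc[f"microbe_{j}", s] = 1
        table.loc["mito_light", s] = math.ceil(m / 2)
        table.loc["mito_dark", s] = m // 2
    origin = {f"microbe_{j}": ("bacteria", f"Microbe_{j}")
              for j in range(n_microbes)}
    origin["mito_light"] = ("organelle", "light", False)
    origin["mito_dark"] = ("organelle", "dark", True)
    truth = StudyTruth(
        feature_origin=origin,
        sample_group={s: "all" for s in samples},
        organelle_load={s: (m / (m + n_microbes) if m + n_microbes else 0.0)
                        for s, m in zip(samples, organelle_counts)})
    return table, truth


def fig1_apparent_abundance(table: pd.DataFrame,
                            focal: str = "microbe_0") -> pd.DataFrame:
    """Apparent focal-microbe relative abundance per community under three
    scenarios: no filtering, partial filtering (dark variant removed only),
    perfect filtering (both organelle variants removed)."""
    rows = {}
    for scenario, drop in (("no_filter", []),
                           ("partial_filter", ["mito_dark"]),
                           ("perfect_filter", ["mito_light", "mito_dark"])):
        sub = table.drop(index=[f for f in drop if f in table.index])
        rows[scenario] = sub.loc[focal] / sub.sum(axis=0)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# multi-sample study

def simulate_study(spec: SimSpec, reference: ReferenceDB,
                   pool: list[SequenceRecord], base_subset: list[str]
                   ) -> tuple[dict, pd.DataFrame, pd.DataFrame, StudyTruth]:
    """A two-(or more-)group study whose groups share one true bacterial
    community but differ in organelle load, with organelle reads drawn
    preferentially from cryptic variants and light per-base sequencing error.

    Returns (queries per sample, feature table, metadata, truth). Queries
    and features are unique read sequences (ASV-style).
    """
    rng = np.random.default_rng(spec.seed + 2)
    species_ids = reference.ids()
    species_seqs = {fid: reference.record(fid).seq for fid in species_ids}
    base_props = rng.dirichlet(np.ones(len(species_ids)))
    base_set = set(base_subset)
    variant_cores = {rec.id: organelle_core(rec) for rec in pool}
    pool_ids = [rec.id for rec in pool]
    if pool_ids:
        weights = np.array([1.0 if rec.id in base_set else spec.cryptic_preference
                            for rec in pool])
        weights = weights / weights.sum()
    else:
        weights = np.zeros(0)

    counts: dict[str, dict[str, int]] = {}
    feature_seq: dict[str, str] = {}
    origin: dict[str, tuple] = {}
    sample_group: dict[str, str] = {}
    load_truth: dict[str, float] = {}
    queries: dict[str, list[SequenceRecord]] = {}

    for group, load in sorted(spec.organelle_load_by_group.items()):
        if load > 1:
            raise ValueError(f"organelle load {load} > 1 for group {group!r}")
        for i in range(spec.n_samples_per_group):
            sample = f"{group}_{i:02d}"
            sample_group[sample] = group
            n_org = rng.binomial(spec.reads_per_sample, load)
            n_bact = spec.reads_per_sample - n_org
            load_truth[sample] = n_org / spec.reads_per_sample
            alpha = spec.dirichlet_concentration * base_props
            p = rng.dirichlet(alpha)
            bact_draw = rng.multinomial(n_bact, p)
            if n_org and not pool_ids:
                raise ValueError("organelle load > 0 but no organelle pool given")
            org_draw = rng.multinomial(n_org, weights) if pool_ids else []
            col: dict[str, int] = {}
            for fid, c in zip(species_ids, bact_draw):
                for _ in range(int(c)):
                    read = _apply_errors(rng, species_seqs[fid],
                                         spec.sequencing_error_rate)
                    feat = _feature_id(read)
                    feature_seq[feat] = read
                    if feat not in origin:
                        lin = format_lineage(reference.lineage(fid))
                        origin[feat] = ("bacteria", lin)
                    col[feat] = col.get(feat, 0) + 1
            for vid, c in zip(pool_ids, org_draw):
                for _ in range(int(c)):
                    read = _apply_errors(rng, variant_cores[vid],
                                         spec.sequencing_error_rate)
                    feat = _feature_id(read)
                    feature_seq[feat] = read
                    if feat not in origin:
                        origin[feat] = ("organelle", vid, vid not in base_set)
                    col[feat] = col.get(feat, 0) + 1
            counts[sample] = col

    features = sorted(feature_seq)
    table = pd.DataFrame(0, index=features, columns=list(counts))
    for sample, col in counts.items():
        for feat, c in col.items():
            table.loc[feat, sample] = c
    for sample in table.columns:
        present = table.index[table[sample] > 0]
        queries[sample] = [SequenceRecord(f, feature_seq[f]) for f in present]
    metadata = pd.DataFrame({"group": pd.Series(sample_group)})
    metadata.index.name = "#SampleID"
    truth = StudyTruth(feature_origin=origin, sample_group=sample_group,
                       organelle_load=load_truth)
    return queries, table, metadata, truth


def study_query_records(table: pd.DataFrame, truth: StudyTruth,
                        queries: dict) -> list[SequenceRecord]:
    """The unique feature sequences of a study as one deduplicated list."""
    seen = {}
    for recs in queries.values():
        for rec in recs:
            seen[rec.id] = rec
    return [seen[f] for f in table.index if f in seen]


# ---------------------------------------------------------------------------
# negative-control fixtures

def shuffle_sequences(records: list[SequenceRecord], seed: int = 0
                      ) -> list[SequenceRecord]:
    """Per-character uniform shuffle of each sequence (ids suffixed .shuf)."""
    if not records:
        raise ValueError("records must be non-empty")
    rng = np.random.default_rng(seed)
    out = []
    for rec in records:
        arr = np.array(list(rec.seq))
        rng.shuffle(arr)
        out.append(SequenceRecord(rec.id + ".shuf", "".join(arr),
                                  rec.description))
    return out


def generate_mock_fixture(spec: SimSpec, reference: ReferenceDB
                          ) -> tuple[dict, pd.DataFrame, StudyTruth]:
    """An organelle-free mock study: bacterial reads only."""
    mock_spec = SimSpec(**{**spec.__dict__,
                           "organelle_load_by_group": {"mock": 0.0}})
    queries, table, _, truth = simulate_study(mock_spec, reference, [], [])
    return queries, table, truth
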