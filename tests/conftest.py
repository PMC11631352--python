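import numpy as np
import pandas as pd
import pytest

from organaudit.io import SequenceRecord
from organaudit.lineage import Lineage
from organaudit.refdb import PrimerPair, ReferenceDB, reverse_complement
from organaudit.simulate import SimSpec, generate_organelle_pool, generate_reference

# toy primers whose sites are easy to embed by hand
TOY_F = "ACGTACGTAC"
TOY_R = "TTGGCCAATT"


@pytest.fixture(scope="session")
def toy_primers():
    return PrimerPair(TOY_F, TOY_R, min_amplicon_len=4, max_amplicon_len=100)


def make_amplicon_record(rec_id: str, core: str, flank5="AAAA", flank3="TTTT"):
    """A record carrying toy primer sites around ``core``."""
    return SequenceRecord(rec_id, flank5 + TOY_F + core + reverse_complement(TOY_R)
                          + flank3)


@pytest.fixture(scope="session")
def tiny_db():
    """Five handcrafted bacterial entries, silva dialect."""
    rng = np.random.default_rng(7)
    db = ReferenceDB("silva")
    lineages = [
        ("Bacteria", "Proteobacteria", "Gammaproteobacteria", "Enterobacterales",
         "Enterobacteriaceae", "Escherichia", "coli"),
        ("Bacteria", "Proteobacteria", "Gammaproteobacteria", "Enterobacterales",
         "Enterobacteriaceae", "Salmonella", "enterica"),
        ("Bacteria", "Firmicutes", "Bacilli", "Lactobacillales",
         "Streptococcaceae", "Streptococcus", "mutans"),
        ("Bacteria", "Bacteroidota", "Bacteroidia", "Bacteroidales",
         "Bacteroidaceae", "Bacteroides", "fragilis"),
        ("Archaea", "Euryarchaeota", "Methanobacteria", "Methanobacteriales",
         "Methanobacteriaceae", "Methanobrevibacter", "smithii"),
    ]
    for i, labels in enumerate(lineages):
        seq = "".join(rng.choice(list("ACGT"), size=150))
        db.add(SequenceRecord(f"ref{i}", seq), Lineage(labels, "silva"))
    return db


@pytest.fixture(scope="session")
def small_spec():
    return SimSpec(n_phyla=2, genera_per_phylum=2, species_per_genus=2,
                   seq_len=120, organelle_pool_size=4,
                   n_samples_per_group=3, reads_per_sample=60, seed=42)


@pytest.fixture(scope="session")
def small_reference(small_spec):
    return generate_reference(small_spec)


@pytest.fixture(scope="session")
def small_pool(small_spec, small_reference):
    db, _ = small_reference
    return generate_organelle_pool(small_spec, db)


def random_feature_table(rng, n_features=8, n_samples=4, max_count=50):
    counts = rng.integers(0, max_count, size=(n_features, n_samples))
    return pd.DataFrame(counts,
                        index=[f"f{i}" for i in range(n_features)],
                        columns=[f"s{j}" for j in range(n_samples)])
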