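import numpy as np
import pytest

import tcwsig as t


@pytest.fixture
def tiny_genome():
    """ATCAT carries a single plus-strand TCA site at position 3."""
    return t.Genome({"chr1": "ATCAT"})


@pytest.fixture
def rng():
    return np.random.default_rng(20210701)


@pytest.fixture(scope="session")
def shared_genome():
    """One 100 kb random genome shared by simulation-heavy tests."""
    return t.make_genome(100_000, 0.45, seed=11)


def random_catalog(genome, n_records, rng, sample_ids=("S1", "S2")):
    """Random valid SNVs drawn against a genome (REF always matches)."""
    chrom = list(genome.sequences)[0]
    seq = genome.sequences[chrom]
    records = []
    while len(records) < n_records:
        pos = int(rng.integers(1, len(seq) + 1))
        ref = seq[pos - 1]
        if ref == "N":
            continue
        alt = rng.choice([b for b in "ACGT" if b != ref])
        sample = str(rng.choice(list(sample_ids)))
        records.append(t.MutationRecord(sample, chrom, pos, ref, str(alt)))
    return t.MutationCatalog.from_records(records)


def brute_force_is_apobec(genome, record):
    """Independent two-strand oracle: enumerate both strand readings
    literally and test TCW + C>T/C>G on each."""
    seq = genome.sequences[record.chrom]
    if record.pos < 2 or record.pos > len(seq) - 1:
        return None  # non-classifiable
    triplet = seq[record.pos - 2 : record.pos + 1]
    if "N" in triplet or record.alt == "N":
        return None
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    readings = [
        (triplet, record.ref, record.alt),
        (
            "".join(comp[b] for b in reversed(triplet)),
            comp[record.ref],
            comp[record.alt],
        ),
    ]
    for trip, ref, alt in readings:
        if ref != trip[1]:
            continue
        if trip[0] == "T" and trip[1] == "C" and trip[2] in "AT" and alt in "TG":
            return True
    return False
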