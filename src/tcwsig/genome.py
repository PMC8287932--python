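"""Reference genomes, somatic SNV catalogs and trinucleotide contexts.

Coordinates are 1-based everywhere (VCF/MAF convention): a
:class:`MutationRecord` at ``pos`` mutates the ``pos``-th base of its
chromosome, and its trinucleotide context is the plus-strand triplet at
``(pos-1, pos, pos+1)``.  Internal numpy views are 0-based; the conversion
happens only at the array boundary inside this module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger("tcwsig")

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

# numeric base codes; complement(b) == 3 - b for the four real bases
BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
CODE_BASE = "ACGTN"
_ENCODE_TABLE = np.full(256, 4, dtype=np.uint8)
for _b, _c in BASE_CODE.items():
    _ENCODE_TABLE[ord(_b)] = _c
    _ENCODE_TABLE[ord(_b.lower())] = _c


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N maps to N)."""
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def encode_bases(seq) -> np.ndarray:
    """Encode a nucleotide string or array of single bases as uint8 codes."""
    if isinstance(seq, str):
        return _ENCODE_TABLE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    arr = np.asarray(seq, dtype="U1")
    return _ENCODE_TABLE[arr.view(np.uint32).astype(np.uint8)]


class RefMismatchError(ValueError):
    """A mutation record's REF base disagrees with the reference genome."""


class GenomeFormatError(ValueError):
    """The FASTA input violates the genome contract."""


@dataclass
class Genome:
    """An in-memory reference genome: chromosome name -> uppercase sequence.

    Sequences are normalized to uppercase on construction; characters outside
    ``{A,C,G,T,N}`` are mapped to ``N``.
    """

    sequences: dict[str, str]
    _encoded: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        norm: dict[str, str] = {}
        for name, seq in self.sequences.items():
            if not seq:
                raise GenomeFormatError(f"empty sequence for chromosome {name!r}")
            seq = seq.upper()
            if any(b not in BASE_CODE for b in set(seq)):
                seq = "".join(b if b in BASE_CODE else "N" for b in seq)
            norm[name] = seq
        self.sequences = norm

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    def encoded(self, chrom: str) -> np.ndarray:
        """Cached uint8-coded view of a chromosome (A=0 C=1 G=2 T=3 N=4)."""
        arr = self._encoded.get(chrom)
        if arr is None:
            arr = encode_bases(self.sequences[chrom])
            self._encoded[chrom] = arr
        return arr

    def base(self, chrom: str, pos: int) -> str:
        """Reference base at a 1-based position."""
        return self.sequences[chrom][pos - 1]

    def write_fasta(self, path: str | Path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name, seq in self.sequences.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


@dataclass(frozen=True)
class MutationRecord:
    """A single somatic SNV call (1-based position)."""

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.ref not in "ACGT" or self.alt not in "ACGT":
            raise ValueError(f"ref/alt must be single ACGT bases: {self}")
        if self.ref == self.alt:
            raise ValueError(f"alt equals ref: {self}")


TSV_COLUMNS = ["sample", "chrom", "pos", "ref", "alt"]


class MutationCatalog:
    """An ordered collection of somatic SNVs across samples.

    Backed by a pandas DataFrame with columns ``sample chrom pos ref alt``
    so large synthetic cohorts can be classified without per-record Python
    objects; :meth:`records` materialises :class:`MutationRecord` objects on
    demand.
    """

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in TSV_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"mutation table missing columns: {missing}")
        self.frame = frame[TSV_COLUMNS].reset_index(drop=True).astype(
            {"sample": str, "chrom": str, "pos": np.int64, "ref": str, "alt": str}
        )

    @classmethod
    def from_records(cls, records: Iterable[MutationRecord]) -> "MutationCatalog":
        rows = [(r.sample_id, r.chrom, r.pos, r.ref, r.alt) for r in records]
        return cls(pd.DataFrame(rows, columns=TSV_COLUMNS))

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def samples(self) -> list[str]:
        """Distinct sample ids in first-appearance order."""
        return list(dict.fromkeys(self.frame["sample"]))

    def records(self) -> Iterator[MutationRecord]:
        for row in self.frame.itertuples(index=False):
            yield MutationRecord(row.sample, row.chrom, int(row.pos), row.ref, row.alt)

    def write_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    def write_vcf(self, path: str | Path, genome: Genome | None = None) -> None:
        """Write the catalog as a minimal single-sample-column VCF.

        The sample id travels in the ``SAMPLE`` INFO field so multi-sample
        cohorts survive a round trip through one file.
        """
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##INFO=<ID=SAMPLE,Number=1,Type=String,Description="Sample id">\n')
            if genome is not None:
                for name, length in genome.lengths.items():
                    fh.write(f"##contig=<ID={name},length={length}>\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
            for row in self.frame.itertuples(index=False):
                fh.write(
                    f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t"
                    f"SAMPLE={row.sample}\n"
                )


@dataclass(frozen=True)
class TrinucContext:
    """Plus-strand trinucleotide context of a mutated base plus its
    pyrimidine-canonical form.

    ``strand_canonical`` is the same genomic triplet re-expressed with a C or
    T center: reverse-complemented iff the plus-strand center is A or G
    (``flipped``).  ``classifiable`` is False when a flank is N or missing
    (contig edge)."""

    five_prime: str
    center: str
    three_prime: str
    strand_canonical: str
    flipped: bool
    classifiable: bool = True

    @property
    def plus_triplet(self) -> str:
        return self.five_prime + self.center + self.three_prime


def load_genome(path: str | Path) -> Genome:
    """Read a (possibly line-wrapped) multi-record FASTA into a Genome.

    Raises on missing files, duplicate chromosome names and empty records so
    coordinate bugs surface at load time rather than as silent mismatches.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"genome FASTA not found: {path}")
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in sequences:
            raise GenomeFormatError(f"duplicate chromosome name {rec.id!r} in {path}")
        if len(rec.seq) == 0:
            raise GenomeFormatError(f"empty sequence for record {rec.id!r} in {path}")
        sequences[rec.id] = str(rec.seq)
    if not sequences:
        raise GenomeFormatError(f"no FASTA records in {path}")
    return Genome(sequences)


def read_snvs(
    path: str | Path,
    dialect: str = "auto",
    sample_override: str | None = None,
    accept_filters: tuple[str, ...] = ("PASS", "."),
) -> tuple[MutationCatalog, dict]:
    """Read somatic SNVs from a VCF or a MAF-like TSV.

    Parameters
    ----------
    dialect:
        ``"vcf"``, ``"tsv"`` or ``"auto"`` (by file extension).
    sample_override:
        Assign this sample id to every record; required for VCFs that carry
        no usable sample identity.
    accept_filters:
        VCF FILTER values accepted (default PASS / unset); pass ``None``
        via an empty check by supplying all observed values if call-quality
        filtering is not wanted.

    Returns
    -------
    (catalog, qc) where qc counts ``loaded``, ``skipped_non_snv`` and
    ``skipped_filter`` rows.
    """
    path = Path(path)
    if dialect == "auto":
        dialect = "vcf" if path.suffix.lower() == ".vcf" else "tsv"
    if dialect == "tsv":
        return _read_snvs_tsv(path)
    if dialect == "vcf":
        return _read_snvs_vcf(path, sample_override, accept_filters)
    raise ValueError(f"unknown mutation dialect {dialect!r}")


def _read_snvs_tsv(path: Path) -> tuple[MutationCatalog, dict]:
    try:
        table = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValueError(f"unparseable mutation TSV {path}: {exc}") from exc
    missing = [c for c in TSV_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"mutation TSV {path} missing required columns {missing}")
    rows = []
    skipped = 0
    for i, row in enumerate(table.itertuples(index=False), start=2):  # header is line 1
        ref, alt = str(row.ref).upper(), str(row.alt).upper()
        try:
            pos = int(row.pos)
        except (TypeError, ValueError):
            raise ValueError(f"{path}:{i}: non-integer position {row.pos!r}")
        if len(ref) != 1 or len(alt) != 1 or ref not in "ACGT" or alt not in "ACGT":
            skipped += 1
            continue
        if ref == alt:
            raise ValueError(f"{path}:{i}: alt equals ref ({ref})")
        rows.append((str(row.sample), str(row.chrom), pos, ref, alt))
    if skipped:
        logger.info("read_snvs: skipped %d non-SNV rows in %s", skipped, path)
    if not rows:
        logger.warning("read_snvs: no SNVs loaded from %s", path)
    catalog = MutationCatalog(pd.DataFrame(rows, columns=TSV_COLUMNS))
    return catalog, {"loaded": len(rows), "skipped_non_snv": skipped, "skipped_filter": 0}


def _read_snvs_vcf(
    path: Path, sample_override: str | None, accept_filters: tuple[str, ...]
) -> tuple[MutationCatalog, dict]:
    import pysam

    rows = []
    skipped = 0
    skipped_filter = 0
    with pysam.VariantFile(str(path)) as vcf:
        vcf_samples = list(vcf.header.samples)
        if sample_override is None and len(vcf_samples) == 1:
            default_sample = vcf_samples[0]
        else:
            default_sample = sample_override
        for rec in vcf:
            filters = list(rec.filter.keys())
            filt = filters[0] if filters else "."
            if filt not in accept_filters:
                skipped_filter += 1
                continue
            sample = rec.info.get("SAMPLE", default_sample)
            if sample is None:
                raise ValueError(
                    f"{path}: VCF carries no usable sample identity; "
                    "pass sample_override"
                )
            ref = rec.ref.upper()
            for alt in rec.alts or ():
                alt = alt.upper()
                if len(ref) != 1 or len(alt) != 1 or ref not in "ACGT" or alt not in "ACGT":
                    skipped += 1
                    continue
                rows.append((str(sample), rec.chrom, rec.pos, ref, alt))
    if skipped:
        logger.info("read_snvs: skipped %d non-SNV alleles in %s", skipped, path)
    if not rows:
        logger.warning("read_snvs: no SNVs loaded from %s", path)
    catalog = MutationCatalog(pd.DataFrame(rows, columns=TSV_COLUMNS))
    return catalog, {
        "loaded": len(rows),
        "skipped_non_snv": skipped,
        "skipped_filter": skipped_filter,
    }


def context_of(genome: Genome, record: MutationRecord) -> TrinucContext:
    """Plus-strand trinucleotide context of a record, pyrimidine-canonicalized.

    Raises :class:`RefMismatchError` when the record's REF disagrees with the
    genome (the classic 0/1-based off-by-one symptom).  Contig-edge positions
    and N-containing triplets come back with ``classifiable=False`` rather
    than raising.
    """
    seq = genome.sequences.get(record.chrom)
    if seq is None:
        raise KeyError(f"unknown chromosome {record.chrom!r} for {record}")
    if not 1 <= record.pos <= len(seq):
        raise IndexError(f"position out of range for {record}")
    center = seq[record.pos - 1]
    if center != record.ref:
        raise RefMismatchError(
            f"REF mismatch at {record.chrom}:{record.pos}: record says "
            f"{record.ref}, genome has {center} ({record})"
        )
    if record.pos < 2 or record.pos > len(seq) - 1:
        return TrinucContext("N", center, "N", "NNN", False, classifiable=False)
    five, three = seq[record.pos - 2], seq[record.pos]
    triplet = five + center + three
    if "N" in triplet:
        return TrinucContext(five, center, three, "NNN", False, classifiable=False)
    flipped = center in "AG"
    canonical = revcomp(triplet) if flipped else triplet
    return TrinucContext(five, center, three, canonical, flipped, classifiable=True)
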