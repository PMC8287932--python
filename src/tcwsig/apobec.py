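"""APOBEC-signature classification of somatic SNVs.

An APOBEC mutation is a C→T or C→G substitution whose mutated cytosine sits
in a TCW trinucleotide context (W ∈ {A, T}), counted on either strand via
pyrimidine canonicalization: a G→A/G→C on the plus strand whose reverse
complement reads T-C-W is the same deamination event seen from the other
strand.  W is strictly {A, T}; TCC/TCG never qualify.

Per-sample counts carry the display transform ``log10(n_apobec + 0.5)``,
which keeps zero-count tumors finite and — being strictly monotone — leaves
any rank correlation against the counts unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import (
    COMPLEMENT,
    Genome,
    MutationCatalog,
    MutationRecord,
    RefMismatchError,
    context_of,
    encode_bases,
)

logger = logging.getLogger("tcwsig")

# base codes from genome.encode_bases: A=0 C=1 G=2 T=3 N=4; comp(b) = 3 - b
_A, _C, _G, _T, _N = 0, 1, 2, 3, 4


@dataclass(frozen=True)
class ApobecCallResult:
    """Classification of one SNV against the TCW / C→T|C→G definition."""

    record: MutationRecord
    is_apobec: bool
    canonical_context: str
    canonical_change: str
    classifiable: bool


@dataclass(frozen=True)
class SampleMutationSummary:
    """Per-sample mutation tallies plus the log10(n + 0.5) display value."""

    sample_id: str
    n_total: int
    n_classifiable: int
    n_apobec: int

    @property
    def log_shifted(self) -> float:
        return float(np.log10(self.n_apobec + 0.5))


def classify(
    genome: Genome, record: MutationRecord, plus_strand_only: bool = False
) -> ApobecCallResult:
    """Classify a single SNV record.

    The triplet is canonicalized to a pyrimidine center (reverse complement
    when REF is A/G, complementing ALT alongside) and tested against
    T-C-[A|T] with canonical ALT in {T, G}.  ``plus_strand_only`` restricts
    to literal plus-strand TCW (sensitivity analysis only; both-strand
    counting is the field convention).
    """
    ctx = context_of(genome, record)
    if not ctx.classifiable:
        return ApobecCallResult(record, False, "NNN", "", classifiable=False)
    canon_alt = COMPLEMENT[record.alt] if ctx.flipped else record.alt
    canon_ref = ctx.strand_canonical[1]
    change = f"{canon_ref}>{canon_alt}"
    hit = (
        ctx.strand_canonical[0] == "T"
        and canon_ref == "C"
        and ctx.strand_canonical[2] in "AT"
        and canon_alt in "TG"
    )
    if plus_strand_only and ctx.flipped:
        hit = False
    return ApobecCallResult(record, hit, ctx.strand_canonical, change, classifiable=True)


def classify_catalog(
    genome: Genome, catalog: MutationCatalog, plus_strand_only: bool = False
) -> pd.DataFrame:
    """Vectorized classification of a whole catalog.

    Returns the catalog frame with added boolean columns ``classifiable`` /
    ``is_apobec`` and an int column ``channel`` (0..95 index into the
    conventional 96-channel substitution/context table, -1 when
    non-classifiable).  Numerically independent from :func:`classify`'s
    string path; the two are cross-checked in the test suite.
    """
    df = catalog.frame
    n = len(df)
    classifiable = np.zeros(n, dtype=bool)
    is_apobec = np.zeros(n, dtype=bool)
    channel = np.full(n, -1, dtype=np.int64)

    ref_e = encode_bases(df["ref"].to_numpy())
    alt_e = encode_bases(df["alt"].to_numpy())

    for chrom, idx in df.groupby("chrom", sort=False).indices.items():
        seq = genome.encoded(chrom)
        pos = df["pos"].to_numpy()[idx]  # 1-based
        if (pos < 1).any() or (pos > len(seq)).any():
            bad = idx[(pos < 1) | (pos > len(seq))][0]
            raise IndexError(f"position out of range: row {bad} on {chrom}")
        center = seq[pos - 1]
        mism = center != ref_e[idx]
        if mism.any():
            bad = idx[mism][0]
            row = df.iloc[bad]
            raise RefMismatchError(
                f"REF mismatch at {row.chrom}:{row.pos}: record says "
                f"{row.ref}, genome has {'ACGTN'[center[mism][0]]}"
            )
        interior = (pos >= 2) & (pos <= len(seq) - 1)
        left = np.where(interior, seq[np.clip(pos - 2, 0, len(seq) - 1)], _N)
        right = np.where(interior, seq[np.clip(pos, 0, len(seq) - 1)], _N)
        ok = interior & (left != _N) & (center != _N) & (right != _N) & (alt_e[idx] != _N)
        flip = (center == _A) | (center == _G)
        c_center = np.where(flip, 3 - center, center)
        c_left = np.where(flip, 3 - right, left)
        c_right = np.where(flip, 3 - left, right)
        c_alt = np.where(flip, 3 - alt_e[idx], alt_e[idx])
        hit = (
            ok
            & (c_left == _T)
            & (c_center == _C)
            & ((c_right == _A) | (c_right == _T))
            & ((c_alt == _T) | (c_alt == _G))
        )
        if plus_strand_only:
            hit &= ~flip
        classifiable[idx] = ok
        is_apobec[idx] = hit
        # channel: substitutions ordered C>A,C>G,C>T,T>A,T>C,T>G then 4x4
        # contexts alphabetically by (5', 3') flank
        sub = np.where(
            c_center == _C,
            np.select([c_alt == _A, c_alt == _G, c_alt == _T], [0, 1, 2], default=-1),
            np.select([c_alt == _A, c_alt == _C, c_alt == _G], [3, 4, 5], default=-1),
        )
        ch = sub * 16 + c_left * 4 + c_right
        channel[idx] = np.where(ok, ch, -1)

    out = df.copy()
    out["classifiable"] = classifiable
    out["is_apobec"] = is_apobec
    out["channel"] = channel
    return out


def count_per_sample(
    genome: Genome, catalog: MutationCatalog, plus_strand_only: bool = False
) -> pd.DataFrame:
    """Per-sample APOBEC mutation counts.

    One row per distinct sample (zero-APOBEC samples included) with columns
    ``sample n_total n_classifiable n_apobec log_shifted``; the sum of
    ``n_total`` equals the catalog size.
    """
    if len(catalog) == 0:
        logger.warning("count_per_sample: empty mutation catalog")
        return pd.DataFrame(
            columns=["sample", "n_total", "n_classifiable", "n_apobec", "log_shifted"]
        )
    calls = classify_catalog(genome, catalog, plus_strand_only=plus_strand_only)
    grouped = calls.groupby("sample", sort=False)
    out = grouped.agg(
        n_total=("sample", "size"),
        n_classifiable=("classifiable", "sum"),
        n_apobec=("is_apobec", "sum"),
    ).reset_index()
    out["n_classifiable"] = out["n_classifiable"].astype(int)
    out["n_apobec"] = out["n_apobec"].astype(int)
    out["log_shifted"] = np.log10(out["n_apobec"] + 0.5)
    return out


# the four APOBEC channels of the 96-channel table: T[C>G]A, T[C>G]T,
# T[C>T]A, T[C>T]T (substitution-major ordering as in channel_labels)
APOBEC_CHANNELS = (1 * 16 + 3 * 4 + 0, 1 * 16 + 3 * 4 + 3,
                   2 * 16 + 3 * 4 + 0, 2 * 16 + 3 * 4 + 3)


def channel_labels() -> list[str]:
    """The 96 channel names, e.g. ``A[C>A]A``, in the conventional order."""
    subs = ["C>A", "C>G", "C>T", "T>A", "T>C", "T>G"]
    bases = "ACGT"
    return [
        f"{l}[{s}]{r}" for s in subs for l in bases for r in bases
    ]


def context_matrix(genome: Genome, catalog: MutationCatalog) -> pd.DataFrame:
    """Sample × 96-channel count matrix (pyrimidine-canonical contexts).

    Row sums equal ``n_classifiable`` per sample; the four TCW channels sum
    to ``n_apobec`` under the default both-strand counting convention.
    """
    calls = classify_catalog(genome, catalog)
    labels = channel_labels()
    samples = list(dict.fromkeys(calls["sample"]))
    mat = np.zeros((len(samples), 96), dtype=np.int64)
    sample_index = {s: i for i, s in enumerate(samples)}
    ok = calls["channel"].to_numpy() >= 0
    rows = calls["sample"].map(sample_index).to_numpy()[ok]
    cols = calls["channel"].to_numpy()[ok]
    np.add.at(mat, (rows, cols), 1)
    return pd.DataFrame(mat, index=pd.Index(samples, name="sample"), columns=labels)
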