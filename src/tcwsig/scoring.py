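"""Gene-signature summary scores over an expression matrix.

A signature score is the per-sample arithmetic mean of the expression of the
signature genes found in the matrix ("mean" method), or optionally the mean
of per-gene z-scores.  Two signatures ship with the package: a 51-gene
hypoxia metagene (editable text file, largely HIF targets) and the six
hypoxia-inducible p53 target genes (BTG2, CYFIP2, INPP5D, KANK3, PHLDA3,
SULF2), used as a transcriptional readout of severe hypoxia.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("tcwsig")

P53_GENES = frozenset({"BTG2", "CYFIP2", "INPP5D", "KANK3", "PHLDA3", "SULF2"})


@dataclass(frozen=True)
class GeneSignature:
    """A named, non-empty set of gene symbols (matched case-insensitively)."""

    name: str
    symbols: frozenset[str]

    def __post_init__(self) -> None:
        if not self.symbols:
            raise ValueError(f"signature {self.name!r} is empty")
        object.__setattr__(self, "symbols", frozenset(s.upper() for s in self.symbols))


def p53_signature() -> GeneSignature:
    """The built-in six-gene hypoxia-inducible p53 response signature."""
    return GeneSignature("p53genes", P53_GENES)


def hypoxia_signature() -> GeneSignature:
    """The bundled 51-gene hypoxia metagene (editable data file)."""
    with resources.files("tcwsig.data").joinpath("hypoxia_metagene.txt").open() as fh:
        symbols = _parse_gene_set(fh)
    return GeneSignature("hypsig", frozenset(symbols))


def _parse_gene_set(lines) -> list[str]:
    out = []
    for line in lines:
        line = line.split("#", 1)[0].strip()
        if line:
            out.append(line.upper())
    return out


def load_gene_set(path: str | Path, name: str | None = None) -> GeneSignature:
    """Read a plain-text gene set (one symbol per line, ``#`` comments)."""
    path = Path(path)
    with open(path) as fh:
        symbols = _parse_gene_set(fh)
    return GeneSignature(name or path.stem, frozenset(symbols))


class ExpressionMatrix:
    """Gene × sample expression values with case-normalized unique symbols.

    No normalization is applied on load: matrices are taken as already
    normalized, mirroring the use of processed cohort expression data.
    """

    def __init__(self, values: pd.DataFrame, unit: str = "normalized expression"):
        values = values.copy()
        values.index = values.index.astype(str).str.upper()
        if values.index.duplicated().any():
            dups = values.index[values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene symbols after case normalization: {dups}")
        if values.columns.duplicated().any():
            raise ValueError("duplicate sample ids in expression matrix")
        self.values = values.astype(float)
        self.unit = unit

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @classmethod
    def read_tsv(cls, path: str | Path, unit: str = "normalized expression"):
        table = pd.read_csv(path, sep="\t", index_col=0)
        return cls(table, unit=unit)

    def write_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene")


@dataclass
class SignatureScore:
    """Per-sample scores for one signature plus gene-coverage bookkeeping."""

    name: str
    scores: pd.Series
    genes_found: list[str]
    genes_missing: list[str]

    @property
    def coverage(self) -> float:
        total = len(self.genes_found) + len(self.genes_missing)
        return len(self.genes_found) / total


def score_signature(
    matrix: ExpressionMatrix,
    signature: GeneSignature,
    method: str = "mean",
    log2: bool = False,
) -> SignatureScore:
    """Summarize a gene signature into one score per sample.

    method "mean": arithmetic mean over the signature genes present
    (computed over non-missing values per sample).  method "zscore": mean of
    per-gene z-scores (constant genes contribute 0).  ``log2`` applies
    log2(x + 1) before averaging for users whose matrices are on a linear
    scale.
    """
    found = sorted(signature.symbols & set(matrix.genes))
    missing = sorted(signature.symbols - set(matrix.genes))
    if not found:
        raise ValueError(
            f"no genes of signature {signature.name!r} found in expression matrix"
        )
    cov = len(found) / len(signature.symbols)
    if cov < 0.5:
        warnings.warn(
            f"signature {signature.name!r}: only {len(found)}/{len(signature.symbols)} "
            "genes found in matrix",
            stacklevel=2,
        )
    sub = matrix.values.loc[found]
    if log2:
        sub = np.log2(sub + 1.0)
    if method == "mean":
        scores = sub.mean(axis=0, skipna=True)
    elif method == "zscore":
        sd = sub.std(axis=1, ddof=0)
        centered = sub.sub(sub.mean(axis=1), axis=0)
        z = centered.div(sd.replace(0.0, np.nan), axis=0).fillna(0.0)
        # samples with all signature genes missing still come back NaN
        z = z.where(~sub.isna(), np.nan)
        scores = z.mean(axis=0, skipna=True)
    else:
        raise ValueError(f"unknown scoring method {method!r}")
    all_missing = sub.isna().all(axis=0)
    if all_missing.any():
        logger.info(
            "score_signature(%s): %d samples have no non-missing signature genes",
            signature.name,
            int(all_missing.sum()),
        )
        scores[all_missing] = np.nan
    scores.name = signature.name
    return SignatureScore(signature.name, scores, found, missing)


def build_score_table(
    scores: dict[str, pd.Series], summaries: pd.DataFrame
) -> pd.DataFrame:
    """Inner-join signature scores with per-sample mutation summaries.

    ``summaries`` is the frame produced by
    :func:`tcwsig.apobec.count_per_sample`.  Samples with a missing (NaN)
    score are dropped from the join with a log line; an empty intersection
    is an error.
    """
    if not scores:
        raise ValueError("at least one score column is required")
    pieces = []
    for name, series in scores.items():
        if series.index.duplicated().any():
            raise ValueError(f"duplicated sample id in score column {name!r}")
        s = series.dropna()
        if len(s) < len(series):
            logger.info(
                "build_score_table: dropping %d samples with missing %s",
                len(series) - len(s),
                name,
            )
        pieces.append(s.rename(name))
    score_frame = pd.concat(pieces, axis=1, join="inner")
    summ = summaries.set_index("sample")
    table = score_frame.join(summ, how="inner")
    unmatched = len(score_frame) - len(table)
    if unmatched:
        logger.info(
            "build_score_table: %d scored samples lack mutation data", unmatched
        )
    if table.empty:
        raise ValueError("no samples shared between scores and mutation summaries")
    table.index.name = "sample"
    return table
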