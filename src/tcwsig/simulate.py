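"""Synthetic data generation: reference genome, tumor cohort and bench-assay
tables, all with ground-truth labels for recovery testing.

The cohort model operationalizes the causal hypothesis under test: a latent
per-sample hypoxia level ``h_i ~ N(0, 1)`` drives both (a) expression of
hypoxia-signature genes (linear effect plus Gaussian noise) and (b) the
fraction of that sample's somatic mutations that are APOBEC-type,
``f_i = logistic(a + b * h_i)``.  Total mutation burdens are
negative-binomial (overdispersion is the norm for tumor burdens; the
dispersion parameter recovers Poisson as it grows).  APOBEC events are
placed at distinct genomic TCW sites on either strand, emitting the correct
plus-strand REF/ALT via complementation; the remaining events land at
uniform positions with a uniform non-reference ALT.

A background event can coincidentally create a TCW APOBEC mutation; truth
labels record intent.  ``exclude_collisions=True`` forbids such collisions
so that counted and injected APOBEC mutations must agree exactly —
exactness where tested, realism where simulated.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .genome import Genome, MutationCatalog, TSV_COLUMNS
from .scoring import ExpressionMatrix, P53_GENES, hypoxia_signature

logger = logging.getLogger("tcwsig")

MIN_GENOME_LENGTH = 1000
CHROM = "chr1"

_A, _C, _G, _T = 0, 1, 2, 3
_CODE_BASE = "ACGTN"


@dataclass
class CohortParams:
    """Parameters of the synthetic tumor cohort.

    Defaults describe the standard study condition used throughout the test
    suite: 200 samples, a 100 kb uniform-composition genome at GC 0.45, a
    mean burden of 100 mutations/sample with moderate overdispersion, and a
    positive hypoxia->APOBEC coupling (a=-1, b=1) giving APOBEC fractions
    around 0.27 in an average-hypoxia tumor.
    """

    n_samples: int = 200
    genome_length: int = 100_000
    gc_fraction: float = 0.45
    mean_mutations: float = 100.0  # negative-binomial mean per sample
    dispersion: float = 2.0  # NB shape k; larger -> closer to Poisson
    intercept: float = -1.0  # a in f = logistic(a + b*h)
    slope: float = 1.0  # b, the hypoxia->APOBEC coupling
    baseline_expression: float = 8.0  # per-gene baseline mu (log2-like units)
    hypoxia_effect: float = 1.0  # beta on hypoxia-signature genes
    p53_effect: float = 0.5  # beta on the six p53 response genes
    noise_sigma: float = 1.0  # expression noise SD
    n_filler_genes: int = 100
    ct_split: float = 0.7  # P(C->T) per APOBEC event; rest are C->G
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_length < MIN_GENOME_LENGTH:
            raise ValueError(
                f"genome_length must be >= {MIN_GENOME_LENGTH} "
                "(too few TCW sites for injection)"
            )
        if not 0.0 < self.gc_fraction < 1.0:
            raise ValueError("gc_fraction must be in (0, 1)")
        if self.mean_mutations <= 0 or self.dispersion <= 0:
            raise ValueError("mean_mutations and dispersion must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if not 0.0 <= self.ct_split <= 1.0:
            raise ValueError("ct_split must be a probability")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")


@dataclass
class CohortTruth:
    """Ground truth of a simulated cohort."""

    hypoxia: pd.Series  # latent h_i per sample
    apobec_fraction: pd.Series  # f_i per sample
    apobec_count: pd.Series  # injected APOBEC events per sample
    total_count: pd.Series
    mutation_is_apobec: np.ndarray  # intent label per catalog row
    gene_effects: pd.Series  # true beta per gene

    def to_json(self, path: str | Path) -> None:
        payload = {
            "hypoxia": self.hypoxia.to_dict(),
            "apobec_fraction": self.apobec_fraction.to_dict(),
            "apobec_count": {k: int(v) for k, v in self.apobec_count.items()},
            "total_count": {k: int(v) for k, v in self.total_count.items()},
            "mutation_is_apobec": self.mutation_is_apobec.astype(int).tolist(),
            "gene_effects": self.gene_effects.to_dict(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


@dataclass
class SimulatedCohort:
    params: CohortParams
    genome: Genome
    catalog: MutationCatalog
    expression: ExpressionMatrix
    truth: CohortTruth
    exclude_collisions: bool = False

    def write(self, outdir: str | Path) -> dict[str, str]:
        """Write FASTA, mutation TSV + VCF, expression TSV, truth and params
        JSON; returns a name -> path manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": outdir / "genome.fasta",
            "mutations_tsv": outdir / "mutations.tsv",
            "mutations_vcf": outdir / "mutations.vcf",
            "expression": outdir / "expression.tsv",
            "truth": outdir / "truth.json",
            "params": outdir / "params.json",
        }
        self.genome.write_fasta(paths["genome"])
        self.catalog.write_tsv(paths["mutations_tsv"])
        self.catalog.write_vcf(paths["mutations_vcf"], self.genome)
        self.expression.write_tsv(paths["expression"])
        self.truth.to_json(paths["truth"])
        with open(paths["params"], "w") as fh:
            json.dump(
                {**asdict(self.params), "exclude_collisions": self.exclude_collisions},
                fh,
                indent=1,
            )
        return {k: str(v) for k, v in paths.items()}


def make_genome(
    length: int, gc_fraction: float, seed: int | None = None, rng=None
) -> Genome:
    """An i.i.d. random genome: P(C)=P(G)=g/2, P(A)=P(T)=(1-g)/2."""
    if length < MIN_GENOME_LENGTH:
        raise ValueError(f"genome length must be >= {MIN_GENOME_LENGTH}")
    if not 0.0 <= gc_fraction <= 1.0:
        raise ValueError("gc_fraction must be in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    p = [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2]
    codes = rng.choice(4, size=length, p=p)
    seq = "".join(_CODE_BASE[c] for c in codes)
    return Genome({CHROM: seq})


def tcw_site_positions(genome: Genome, chrom: str = CHROM):
    """1-based positions of the mutable C of every TCW site, both strands.

    Returns ``(pos, minus)``: a minus-strand site is a plus-strand
    [A|T]-G-A triplet whose complement reads T-C-W; its mutable base on the
    plus strand is the central G.
    """
    enc = genome.encoded(chrom)
    left, center, right = enc[:-2], enc[1:-1], enc[2:]
    plus = (left == _T) & (center == _C) & ((right == _A) | (right == _T))
    minus = ((left == _A) | (left == _T)) & (center == _G) & (right == _A)
    pos = np.arange(2, len(enc))  # 1-based position of the central base
    sites_pos = np.concatenate([pos[plus], pos[minus]])
    sites_minus = np.concatenate(
        [np.zeros(plus.sum(), dtype=bool), np.ones(minus.sum(), dtype=bool)]
    )
    order = np.argsort(sites_pos, kind="stable")
    return sites_pos[order], sites_minus[order]


def _is_apobec_codes(enc: np.ndarray, pos: np.ndarray, alt: np.ndarray) -> np.ndarray:
    """Vectorized TCW/C->T|C->G test on coded positions (1-based, interior)."""
    left, center, right = enc[pos - 2], enc[pos - 1], enc[pos]
    flip = (center == _A) | (center == _G)
    c_center = np.where(flip, 3 - center, center)
    c_left = np.where(flip, 3 - right, left)
    c_right = np.where(flip, 3 - left, right)
    c_alt = np.where(flip, 3 - alt, alt)
    return (
        (c_left == _T)
        & (c_center == _C)
        & ((c_right == _A) | (c_right == _T))
        & ((c_alt == _T) | (c_alt == _G))
    )


def simulate_cohort(
    params: CohortParams,
    exclude_collisions: bool = False,
    genome: Genome | None = None,
    outdir: str | Path | None = None,
) -> SimulatedCohort:
    """Simulate a full tumor cohort (genome, mutations, expression, truth).

    A pre-built ``genome`` may be supplied to share one reference across
    replicate cohorts; otherwise one is drawn from the params.  With
    ``outdir`` the cohort is also written to disk.  Identical params + seed
    (+ genome) give byte-identical outputs.
    """
    rng = np.random.default_rng(params.seed)
    if genome is None:
        genome = make_genome(params.genome_length, params.gc_fraction, rng=rng)
    enc = genome.encoded(CHROM)
    length = len(enc)
    site_pos, site_minus = tcw_site_positions(genome)
    if len(site_pos) < 10 * params.mean_mutations:
        raise ValueError(
            f"genome has {len(site_pos)} TCW sites; need >= 10x mean burden "
            f"({10 * params.mean_mutations:.0f}) for APOBEC injection"
        )

    n = params.n_samples
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    h = rng.standard_normal(n)
    f = expit(params.intercept + params.slope * h)
    k = params.dispersion
    totals = rng.negative_binomial(k, k / (k + params.mean_mutations), size=n)
    totals = np.maximum(totals, 1)  # a tumor with zero calls never enters a catalog
    n_apo = rng.binomial(totals, f)

    samples_col: list[str] = []
    pos_col: list[np.ndarray] = []
    ref_col: list[np.ndarray] = []
    alt_col: list[np.ndarray] = []
    intent: list[np.ndarray] = []

    for i in range(n):
        m, total = int(n_apo[i]), int(totals[i])
        idx = rng.choice(len(site_pos), size=m, replace=False)
        apo_pos = site_pos[idx]
        apo_minus = site_minus[idx]
        to_t = rng.random(m) < params.ct_split  # C->T vs C->G on the C strand
        ref = np.where(apo_minus, _G, _C).astype(np.uint8)
        alt = np.where(
            apo_minus, np.where(to_t, _A, _C), np.where(to_t, _T, _G)
        ).astype(np.uint8)

        nb = total - m
        used = set(apo_pos.tolist())
        bg_pos = np.empty(0, dtype=np.int64)
        bg_alt = np.empty(0, dtype=np.uint8)
        while len(bg_pos) < nb:
            need = nb - len(bg_pos)
            cand = rng.integers(2, length, size=max(need * 2, 8))  # interior 1-based
            cand_ref = enc[cand - 1]
            cand_alt = ((cand_ref + rng.integers(1, 4, size=len(cand))) % 4).astype(
                np.uint8
            )
            keep = np.ones(len(cand), dtype=bool)
            if exclude_collisions:
                keep &= ~_is_apobec_codes(enc, cand, cand_alt)
            # one substitution per site per sample
            fresh = np.array([p not in used for p in cand.tolist()])
            keep &= fresh
            # drop within-batch duplicates
            _, first = np.unique(cand, return_index=True)
            dup_mask = np.zeros(len(cand), dtype=bool)
            dup_mask[first] = True
            keep &= dup_mask
            cand, cand_alt = cand[keep][:need], cand_alt[keep][:need]
            used.update(cand.tolist())
            bg_pos = np.concatenate([bg_pos, cand])
            bg_alt = np.concatenate([bg_alt, cand_alt])

        all_pos = np.concatenate([apo_pos, bg_pos])
        all_ref = np.concatenate([ref, enc[bg_pos - 1]])
        all_alt = np.concatenate([alt, bg_alt])
        order = np.argsort(all_pos, kind="stable")
        samples_col.extend([sample_ids[i]] * total)
        pos_col.append(all_pos[order])
        ref_col.append(all_ref[order])
        alt_col.append(all_alt[order])
        flag = np.zeros(total, dtype=bool)
        flag[:m] = True
        intent.append(flag[order])

    pos_all = np.concatenate(pos_col)
    base_lookup = np.array(list("ACGTN"))
    frame = pd.DataFrame(
        {
            "sample": samples_col,
            "chrom": CHROM,
            "pos": pos_all,
            "ref": base_lookup[np.concatenate(ref_col)],
            "alt": base_lookup[np.concatenate(alt_col)],
        },
        columns=TSV_COLUMNS,
    )
    catalog = MutationCatalog(frame)

    hyp_genes = sorted(hypoxia_signature().symbols)
    p53_genes = sorted(P53_GENES)
    filler = [f"FILLER{i + 1:04d}" for i in range(params.n_filler_genes)]
    genes = hyp_genes + p53_genes + filler
    betas = np.concatenate(
        [
            np.full(len(hyp_genes), params.hypoxia_effect),
            np.full(len(p53_genes), params.p53_effect),
            np.zeros(len(filler)),
        ]
    )
    noise = (
        rng.standard_normal((len(genes), n)) * params.noise_sigma
        if params.noise_sigma > 0
        else np.zeros((len(genes), n))
    )
    values = params.baseline_expression + betas[:, None] * h[None, :] + noise
    expression = ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=sample_ids),
        unit="synthetic normalized expression",
    )

    sidx = pd.Index(sample_ids, name="sample")
    truth = CohortTruth(
        hypoxia=pd.Series(h, index=sidx, name="hypoxia"),
        apobec_fraction=pd.Series(f, index=sidx, name="apobec_fraction"),
        apobec_count=pd.Series(n_apo, index=sidx, name="apobec_count"),
        total_count=pd.Series(totals, index=sidx, name="total_count"),
        mutation_is_apobec=np.concatenate(intent),
        gene_effects=pd.Series(betas, index=genes, name="beta"),
    )
    cohort = SimulatedCohort(params, genome, catalog, expression, truth,
                             exclude_collisions)
    if outdir is not None:
        cohort.write(outdir)
    return cohort


@dataclass
class CellConditionSpec:
    """Per-condition generative model for the immunofluorescence tables.

    Foci counts per channel are negative-binomial (mean per channel, shared
    dispersion); nuclear areas are lognormal, with replication-catastrophe
    double-positive cells scaled by ``area_multiplier`` to emulate the
    enlarged nuclei of damaged cells.
    """

    foci_means: dict[str, float] = field(
        default_factory=lambda: {"53BP1": 2.0, "RPA": 2.0}
    )
    foci_dispersion: float = 2.0
    area_log_mean: float = float(np.log(100.0))  # arbitrary area units
    area_log_sd: float = 0.25
    area_multiplier: float = 1.0
    n_cells: int = 300

    def __post_init__(self) -> None:
        if self.foci_dispersion <= 0:
            raise ValueError("foci_dispersion must be positive")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")


def simulate_cell_assay(
    conditions: dict[str, CellConditionSpec],
    seed: int = 0,
    thresholds: dict[str, int] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Simulate a per-cell foci/area table across conditions.

    Returns (cell table, truth); truth records the specs and the realized
    double-positive flags per condition.  Deterministic under the seed.
    """
    from .assays import DEFAULT_FOCI_THRESHOLDS

    thresholds = dict(DEFAULT_FOCI_THRESHOLDS, **(thresholds or {}))
    rng = np.random.default_rng(seed)
    rows = []
    truth: dict = {"seed": seed, "conditions": {}}
    for name, spec in conditions.items():
        counts = {}
        for channel, mean in spec.foci_means.items():
            if mean <= 0:
                counts[channel] = np.zeros(spec.n_cells, dtype=np.int64)
            else:
                k = spec.foci_dispersion
                counts[channel] = rng.negative_binomial(
                    k, k / (k + mean), size=spec.n_cells
                )
        area = rng.lognormal(spec.area_log_mean, spec.area_log_sd, size=spec.n_cells)
        double = np.ones(spec.n_cells, dtype=bool)
        for channel, thr in thresholds.items():
            double &= counts.get(channel, np.zeros(spec.n_cells, dtype=np.int64)) > thr
        area = np.where(double, area * spec.area_multiplier, area)
        for j in range(spec.n_cells):
            rows.append(
                {
                    "cell_id": f"{name}_{j + 1:04d}",
                    "condition": name,
                    **{ch: int(counts[ch][j]) for ch in counts},
                    "nuclear_area": float(area[j]),
                }
            )
        truth["conditions"][name] = {
            "spec": asdict(spec),
            "n_double_positive": int(double.sum()),
        }
    return pd.DataFrame(rows), truth


def simulate_ct_table(
    target_gene: str,
    true_folds: dict[str, float],
    control_gene: str = "18S",
    reference_condition: str = "normoxia",
    n_replicates: int = 3,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a qPCR Ct table whose ddCt fold changes center on
    ``true_folds`` (reference condition fold forced to 1)."""
    rng = np.random.default_rng(seed)
    folds = dict(true_folds)
    folds.setdefault(reference_condition, 1.0)
    rows = []
    for rep in range(1, n_replicates + 1):
        rep_shift = rng.normal(0, 0.3)  # block effect, cancels in ddCt
        for condition, fold in folds.items():
            ct_control = 10.0 + rep_shift + rng.normal(0, noise_sd)
            ct_target = (
                25.0 + rep_shift - np.log2(fold) + rng.normal(0, noise_sd)
            )
            rows.append((control_gene, condition, rep, ct_control))
            rows.append((target_gene, condition, rep, ct_target))
    return pd.DataFrame(rows, columns=["gene", "condition", "replicate", "Ct"])


def simulate_lane_table(
    relative_products: dict[str, float],
    reference_condition: str = "normoxia",
    n_replicates: int = 3,
    total_intensity: float = 1000.0,
    noise_sd: float = 0.02,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate deamination-gel lanes whose product intensities center on
    ``relative_products`` times the reference product intensity."""
    rng = np.random.default_rng(seed)
    rel = dict(relative_products)
    rel.setdefault(reference_condition, 1.0)
    base_p = 0.25 * total_intensity  # reference product band
    rows = []
    for condition, r in rel.items():
        for rep in range(1, n_replicates + 1):
            p = base_p * r * (1 + rng.normal(0, noise_sd))
            p = min(max(p, 0.0), total_intensity)
            rows.append((condition, rep, total_intensity - p, p))
    return pd.DataFrame(rows, columns=["condition", "replicate", "S", "P"])
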