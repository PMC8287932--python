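"""End-to-end orchestration: simulate/load -> count -> score -> correlate ->
report, with a validated run configuration and a machine-readable manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .apobec import context_matrix, count_per_sample
from .correlate import correlate_panel, filter_cohorts
from .genome import load_genome, read_snvs
from .scoring import (
    ExpressionMatrix,
    build_score_table,
    hypoxia_signature,
    load_gene_set,
    p53_signature,
    score_signature,
)
from .simulate import CohortParams, simulate_cohort

logger = logging.getLogger("tcwsig")


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run.

    Either ``simulate`` holds :class:`CohortParams` overrides, or
    ``genome``/``mutations`` (and optionally ``expression``) point at input
    files.  Unknown keys in a config file are rejected outright.
    """

    outdir: str
    seed: int = 0
    simulate: dict | None = None
    exclude_collisions: bool = False
    genome: str | None = None
    mutations: str | None = None
    mutations_dialect: str = "auto"
    sample_override: str | None = None
    expression: str | None = None
    hypoxia_gene_set: str | None = None  # None -> bundled metagene
    score_method: str = "mean"
    log2_expression: bool = False
    plus_strand_only: bool = False
    min_n: int = 100
    skip_expression: bool = False
    write_context_matrix: bool = True
    extra_y_cols: list[str] = field(default_factory=list)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ValueError(f"config {path} is not a mapping")
        return cls.from_dict(raw)

    def validate(self) -> None:
        if self.simulate is None:
            if self.genome is None or self.mutations is None:
                raise ValueError(
                    "config needs either 'simulate' params or both 'genome' "
                    "and 'mutations' paths"
                )
            for key in ("genome", "mutations", "expression", "hypoxia_gene_set"):
                path = getattr(self, key)
                if path is not None and not Path(path).exists():
                    raise FileNotFoundError(f"config {key}: no such file {path!r}")
        if self.min_n < 0:
            raise ValueError("min_n must be >= 0")


def run(config: RunConfig) -> dict:
    """Execute the pipeline; returns the manifest dict.

    Outputs under ``config.outdir``: ``apobec_counts.tsv``, ``scores.tsv``,
    ``correlations.tsv``, ``context_matrix.tsv``, ``qc.json``,
    ``manifest.json`` and the resolved ``config.json``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}
    qc: dict = {}

    def _stage(name):
        def wrap(fn, *args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrap

    # --- inputs -----------------------------------------------------------
    if config.simulate is not None:
        params = _stage("simulate")(
            lambda: CohortParams(**{"seed": config.seed, **config.simulate})
        )
        cohort = _stage("simulate")(
            simulate_cohort, params, exclude_collisions=config.exclude_collisions
        )
        genome, catalog, expression = cohort.genome, cohort.catalog, cohort.expression
        sim_paths = _stage("simulate")(cohort.write, outdir / "simulated")
        outputs.update({f"simulated_{k}": v for k, v in sim_paths.items()})
        qc["mutations"] = {"loaded": len(catalog), "skipped_non_snv": 0,
                           "skipped_filter": 0}
    else:
        genome = _stage("load_genome")(load_genome, config.genome)
        catalog, mut_qc = _stage("read_snvs")(
            read_snvs,
            config.mutations,
            dialect=config.mutations_dialect,
            sample_override=config.sample_override,
        )
        qc["mutations"] = mut_qc
        expression = None
        if config.expression is not None and not config.skip_expression:
            expression = _stage("read_expression")(
                ExpressionMatrix.read_tsv, config.expression
            )

    # --- APOBEC counting --------------------------------------------------
    counts = _stage("count_apobec")(
        count_per_sample, genome, catalog, plus_strand_only=config.plus_strand_only
    )
    counts_path = outdir / "apobec_counts.tsv"
    counts.to_csv(counts_path, sep="\t", index=False)
    outputs["apobec_counts"] = str(counts_path)
    qc["samples"] = len(counts)
    qc["non_classifiable"] = int((counts["n_total"] - counts["n_classifiable"]).sum())

    # --- signature scoring + correlation ----------------------------------
    if not config.skip_expression and expression is not None:
        hyp = (
            load_gene_set(config.hypoxia_gene_set, "hypsig")
            if config.hypoxia_gene_set
            else hypoxia_signature()
        )
        hyp_score = _stage("score")(
            score_signature, expression, hyp, config.score_method,
            config.log2_expression,
        )
        scores = {"hypsig": hyp_score.scores}
        qc["hypsig_coverage"] = hyp_score.coverage
        try:
            p53_score = score_signature(
                expression, p53_signature(), config.score_method,
                config.log2_expression,
            )
            scores["p53genes"] = p53_score.scores
            qc["p53genes_coverage"] = p53_score.coverage
        except ValueError:
            logger.info("run: no p53 signature genes in matrix; skipping p53 score")
        table = _stage("score_table")(build_score_table, scores, counts)
        _stage("cohort_filter")(filter_cohorts, {"cohort": table}, config.min_n)
        scores_path = outdir / "scores.tsv"
        table.to_csv(scores_path, sep="\t")
        outputs["scores"] = str(scores_path)

        y_cols = ["n_apobec", "log_shifted", *config.extra_y_cols]
        panel = _stage("correlate")(
            correlate_panel, table, [c for c in scores], y_cols
        )
        corr_path = outdir / "correlations.tsv"
        panel.to_csv(corr_path, sep="\t", index=False)
        outputs["correlations"] = str(corr_path)

    if config.write_context_matrix:
        mat = _stage("context_matrix")(context_matrix, genome, catalog)
        mat_path = outdir / "context_matrix.tsv"
        mat.to_csv(mat_path, sep="\t")
        outputs["context_matrix"] = str(mat_path)

    # --- report -----------------------------------------------------------
    qc_path = outdir / "qc.json"
    with open(qc_path, "w") as fh:
        json.dump(qc, fh, indent=1)
    outputs["qc"] = str(qc_path)

    config_path = outdir / "config.json"
    with open(config_path, "w") as fh:
        json.dump(dataclasses.asdict(config), fh, indent=1)
    outputs["config"] = str(config_path)

    manifest = {
        "tool": "tcwsig",
        "version": __version__,
        "seed": config.seed,
        "outputs": outputs,
        "config": dataclasses.asdict(config),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
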