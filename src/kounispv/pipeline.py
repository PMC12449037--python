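"""End-to-end orchestration: generate/read -> cohort -> signals ->
comparisons -> model, with deterministic table emission.

Every stage is a pure function of its inputs, so a fixed configuration and
seed give byte-identical output trees.  All thresholds (SMQ codes, the KS
PT, the screening alpha, the VIF cut-off) are surfaced in
:class:`RunConfig` with defaults matching the published analysis.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import comparison as cmp
from .cohort import (
    DEFAULT_SMQ_A,
    DEFAULT_SMQ_B,
    KS_PT,
    AttritionTable,
    CohortLabel,
    build_cohort,
    included_cases,
)
from .dictionary import (
    TermDictionary,
    classify_underlying_diseases,
    load_dictionary,
)
from .model import (
    FeatureMatrix,
    ModelFit,
    model_metrics,
    roc_curve,
    select_candidates,
    stepwise_select,
    univariate_screen,
    vif_screen,
)
from .report_io import CaseReport, read_database, write_database
from .signals import detect_signals
from .synthetic import GeneratorConfig, default_dictionary, generate

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.6g"


@dataclass
class RunConfig:
    """Declarative configuration for one pipeline run."""

    out_dir: Path
    seed: int = 0
    # either the four table paths (+ optional dictionary bundle dir) ...
    demo: Path | None = None
    drug: Path | None = None
    reac: Path | None = None
    hist: Path | None = None
    dictionary_dir: Path | None = None
    delimiter: str = ","
    encoding: str = "utf-8"
    # ... or a generator configuration (used when paths are absent)
    generator: GeneratorConfig | None = None
    # analysis thresholds
    smq_a: tuple[int, ...] = DEFAULT_SMQ_A
    smq_b: tuple[int, ...] = DEFAULT_SMQ_B
    ks_pt: int = KS_PT
    alpha: float = 0.05
    vif_threshold: float = 5.0

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        if self.alpha <= 0 or self.vif_threshold <= 0:
            raise ValueError("thresholds must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        gen = raw.pop("generator", None)
        cfg = cls(**{**raw, "out_dir": Path(raw["out_dir"])})
        if gen is not None:
            cfg.generator = GeneratorConfig(**gen)
        return cfg

    def canonical(self) -> str:
        """Canonical JSON of the analysis-relevant configuration.

        ``out_dir`` is excluded: it locates the outputs but does not
        influence them, and the manifest hash must be identical when the
        same analysis is written to two different directories.
        """

        def _default(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            if isinstance(o, (Path, frozenset)):
                return sorted(o) if isinstance(o, frozenset) else str(o)
            raise TypeError(type(o))

        payload = dataclasses.asdict(self)
        payload.pop("out_dir")
        return json.dumps(payload, default=_default, sort_keys=True)


def assemble_features(
    labelled: list[tuple[CaseReport, CohortLabel]],
    dictionary: TermDictionary,
    *,
    smq_a: tuple[int, ...] = DEFAULT_SMQ_A,
    smq_b: tuple[int, ...] = DEFAULT_SMQ_B,
    ks_pt: int = KS_PT,
) -> FeatureMatrix:
    """Binary candidate matrix over the included cohort.

    Columns: the seven disease flags, fatal outcome, one flag per ATC-2
    class in use, and one flag per co-reported candidate PT.  The label is
    1 for non-KS cases.
    """
    included = included_cases(labelled)
    disease_rows = cmp.tabulate_disease_and_death(labelled, dictionary)
    atc2_rows = cmp.tabulate_atc2_use(labelled, dictionary)
    copt_rows = cmp.tabulate_copt_frequencies(
        labelled, dictionary, smq_a=smq_a, smq_b=smq_b, ks_pt=ks_pt
    )
    atc2_classes = [r.feature.removeprefix("atc2_") for r in atc2_rows]
    copt_pts = [
        int(r.feature.removeprefix("pt_"))
        for r in copt_rows
        if r.feature != cmp.ANY_LISTED_FEATURE
    ]
    del disease_rows  # column definitions below recompute per case

    records = []
    labels = []
    for case, lab in included:
        flags = classify_underlying_diseases(dictionary, case.history or frozenset())
        row: dict[str, int] = {
            f"disease_{name}": int(getattr(flags, name))
            for name in flags.FLAGS
        }
        row["death"] = int(case.died)
        classes = set()
        for ing in case.all_ingredients():
            for code in dictionary.ingredient_atc.get(ing, frozenset()):
                classes.add(code[:3])
        for cls in atc2_classes:
            row[f"atc2_{cls}"] = int(cls in classes)
        for pt in copt_pts:
            row[f"pt_{pt}"] = int(pt in case.reactions)
        records.append(row)
        labels.append(1 if lab.group == "nonKS" else 0)
    X = pd.DataFrame.from_records(records)
    if X.empty:
        X = pd.DataFrame(columns=["death"])
    return FeatureMatrix(X=X, y=np.asarray(labels, dtype=float))


def _attrition_frame(att: AttritionTable) -> pd.DataFrame:
    return pd.DataFrame(
        [(k, getattr(att, k)) for k in (
            "total", "n_criterion_a", "n_criterion_b", "n_both",
            "n_excluded", "n_final", "n_ks", "n_nonks",
        )],
        columns=["step", "n"],
    )


def _signals_frame(results) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.atc5, r.ingredient, r.n_cases, r.ror, r.ci_low, r.ci_high,
             r.p_fisher, r.corrected, r.signal)
            for r in results
        ],
        columns=["atc_codes", "ingredient", "n_cases", "ror", "ci_low",
                 "ci_high", "p_fisher", "corrected", "signal"],
    )


def _comparison_frame(rows: list[cmp.GroupCounts]) -> pd.DataFrame:
    out = []
    for gc in rows:
        try:
            res = cmp.compare_counts(gc)
            test, stat, p = res.test_used, res.statistic, res.p
        except cmp.DegenerateTableError:
            test, stat, p = "none", None, float("nan")
        out.append(
            (gc.feature, gc.x_ks, gc.n_ks, gc.x_nonks, gc.n_nonks, test, stat, p)
        )
    return pd.DataFrame(
        out,
        columns=["feature", "x_ks", "n_ks", "x_nonks", "n_nonks",
                 "test", "statistic", "p"],
    )


def _model_frame(fit: ModelFit, metrics: dict[str, float]) -> pd.DataFrame:
    rows = [
        (v.name, v.odds_ratio, v.ci_low, v.ci_high, v.wald_ci_low,
         v.wald_ci_high, v.wald_chi2, v.p, v.vif)
        for v in fit.table
    ]
    rows += [
        (f"[{key}]", metrics[key], None, None, None, None, None, None, None)
        for key in ("pseudo_r2", "aicc", "bic", "auc", "n", "loglik")
    ]
    return pd.DataFrame(
        rows,
        columns=["variable", "odds_ratio", "ci_low", "ci_high",
                 "wald_ci_low", "wald_ci_high", "wald_chi2", "p", "vif"],
    )


def run_pipeline(cfg: RunConfig) -> dict[str, object]:
    """Run every stage and write the output tree under ``cfg.out_dir``.

    Returns the in-memory artifacts (database, attrition, signal and
    comparison tables, model fit) keyed by stage name.
    """
    out = cfg.out_dir
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, object] = {}

    stage = "input"
    try:
        if cfg.demo is not None:
            dictionary = (
                load_dictionary(
                    Path(cfg.dictionary_dir) / "pt.tsv",
                    Path(cfg.dictionary_dir) / "smq.tsv",
                    Path(cfg.dictionary_dir) / "atc.tsv",
                )
                if cfg.dictionary_dir
                else default_dictionary()
            )
            db = read_database(
                cfg.demo, cfg.drug, cfg.reac, cfg.hist,
                delimiter=cfg.delimiter, encoding=cfg.encoding,
            )
            truth = None
        else:
            gen = cfg.generator or GeneratorConfig(seed=cfg.seed)
            dictionary = default_dictionary()
            db, truth = generate(gen, dictionary)
        artifacts["database"] = db
        artifacts["ground_truth"] = truth

        stage = "cohort"
        labelled, attrition = build_cohort(
            db, dictionary, smq_a=cfg.smq_a, smq_b=cfg.smq_b, ks_pt=cfg.ks_pt
        )
        artifacts["attrition"] = attrition
        _attrition_frame(attrition).to_csv(out / "attrition.tsv", sep="\t", index=False)
        logger.info(
            "cohort: %d cases -> %d eligible -> %d included (%d KS / %d non-KS)",
            attrition.total, attrition.n_both, attrition.n_final,
            attrition.n_ks, attrition.n_nonks,
        )

        stage = "signals"
        ks_ids = {c.case_id for c, lab in labelled if lab.group == "KS"}
        nonks_ids = {c.case_id for c, lab in labelled if lab.group == "nonKS"}
        for name, ids in (("ks", ks_ids), ("nonks", nonks_ids)):
            res = detect_signals(ids, db, dictionary)
            artifacts[f"signals_{name}"] = res
            _signals_frame(res).to_csv(
                out / f"signals_{name}.tsv", sep="\t", index=False,
                float_format=FLOAT_FMT,
            )

        stage = "comparison"
        disease = cmp.tabulate_disease_and_death(labelled, dictionary)
        atc2 = cmp.tabulate_atc2_use(labelled, dictionary)
        copt = cmp.tabulate_copt_frequencies(
            labelled, dictionary, smq_a=cfg.smq_a, smq_b=cfg.smq_b, ks_pt=cfg.ks_pt
        )
        for name, rows in (
            ("disease_death", disease), ("atc2_use", atc2), ("copt", copt)
        ):
            artifacts[f"table_{name}"] = rows
            _comparison_frame(rows).to_csv(
                out / f"table_{name}.tsv", sep="\t", index=False,
                float_format=FLOAT_FMT,
            )

        stage = "model"
        features = assemble_features(
            labelled, dictionary, smq_a=cfg.smq_a, smq_b=cfg.smq_b, ks_pt=cfg.ks_pt
        )
        screen = univariate_screen(features, cfg.alpha)
        candidates = select_candidates(screen, cfg.alpha)
        retained, vifs = vif_screen(features, candidates, cfg.vif_threshold)
        fit = stepwise_select(features, retained, vifs=vifs)
        metrics = model_metrics(fit, features)
        artifacts["model_fit"] = fit
        artifacts["model_metrics"] = metrics
        _model_frame(fit, metrics).to_csv(
            out / "model.tsv", sep="\t", index=False, float_format=FLOAT_FMT
        )
        points = roc_curve(fit.fitted, features.y)
        pd.DataFrame(points, columns=["fpr", "tpr"]).to_csv(
            out / "roc.tsv", sep="\t", index=False, float_format=FLOAT_FMT
        )
        artifacts["roc"] = points

        stage = "manifest"
        manifest = {
            "config_sha256": hashlib.sha256(cfg.canonical().encode()).hexdigest(),
            "seed": cfg.seed,
            "n_cases": db.total_count,
            "attrition": {
                k: getattr(attrition, k)
                for k in ("total", "n_both", "n_excluded", "n_final",
                          "n_ks", "n_nonks")
            },
            "n_signal_rows": {
                "ks": len(artifacts["signals_ks"]),
                "nonks": len(artifacts["signals_nonks"]),
            },
            "model_variables": fit.variables,
            "model_auc": metrics["auc"],
        }
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )
        artifacts["manifest"] = manifest
    except Exception as exc:
        if hasattr(exc, "add_note"):
            exc.add_note(f"pipeline stage: {stage}")
        raise
    return artifacts


def simulate_to_dir(
    gen: GeneratorConfig, out_dir: str | Path
) -> dict[str, object]:
    """Generate a database, write the four tables, dictionary bundle, and a
    ground-truth summary under ``out_dir``."""
    from .dictionary import write_dictionary

    out = Path(out_dir)
    dictionary = default_dictionary()
    db, truth = generate(gen, dictionary)
    write_database(db, out)
    write_dictionary(dictionary, out / "dictionary")
    summary = {
        "seed": gen.seed,
        "n_cases": gen.n_cases,
        "n_ks": truth.n_ks,
        "n_nonks": truth.n_nonks,
        "signals": [
            {
                "ingredient": s.ingredient,
                "target_ror": s.target_ror,
                "cells": [s.a, s.b, s.c, s.d],
                "realized_ror": s.realized_ror,
            }
            for s in truth.signals
        ],
    }
    (out / "ground_truth.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )
    return {"database": db, "ground_truth": truth, "dictionary": dictionary}
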